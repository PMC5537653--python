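"""Cluster-based function transfer, marker congruence, and MTase motif scanning.

Function transfer exploits the component structure of the similarity
network: a protein annotated only as "hypothetical protein" that clusters
with functionally annotated proteins inherits the most frequent
non-hypothetical product of its component (lexicographic tie-break, so the
rule is deterministic).  Congruence between marker-based clusterings (e.g.
terminase large subunits vs major capsid proteins) is quantified with the
adjusted Rand index over the phages that carry both markers.  Amino-MTases
are flagged by their catalytic motif IV tetrapeptide NPP(Y/W/F), and each
call is placed relative to the nearest replication-module gene, since
CcrM-mimicking phage methyltransferases characteristically sit next to the
replication system.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from sklearn.metrics import adjusted_rand_score

from viromenet.io_formats import FeatureRecord, ProteinRecord

MTASE_MOTIF_RE = re.compile(r"NPP[YFW]")

#: product keywords marking replication-module genes (case-insensitive substring)
DEFAULT_REPLICATION_KEYWORDS = ("replication",)


@dataclass
class FunctionSuggestion:
    protein_id: str
    suggested_product: str
    source_cluster: str
    n_support: int


@dataclass
class MtaseCall:
    protein_id: str
    motif: str
    motif_position: int  # 1-based residue index of the motif start
    gene_distance_to_replication: Optional[int] = None


@dataclass
class CongruenceReport:
    marker_a: str
    marker_b: str
    n_shared_phages: int
    adjusted_rand: Optional[float]  # None when < 3 shared phages


def transfer_functions(
    partition: Mapping[str, str], proteins: Sequence[ProteinRecord]
) -> list[FunctionSuggestion]:
    """Suggest products for hypothetical proteins from their cluster's majority label.

    Only components containing at least one non-hypothetical member yield
    suggestions; the most frequent non-hypothetical product wins, ties broken
    lexicographically by product string.  Existing annotations are never
    overwritten.
    """
    by_id = {p.protein_id: p for p in proteins}
    missing = set(by_id) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover proteins: {sorted(missing)[:5]}")

    components: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        components.setdefault(partition[p.protein_id], []).append(p)

    suggestions: list[FunctionSuggestion] = []
    for cid, members in components.items():
        labels = Counter(p.product for p in members if not p.is_hypothetical)
        if not labels:
            continue
        best_count = max(labels.values())
        product = min(k for k, v in labels.items() if v == best_count)
        for p in members:
            if p.is_hypothetical:
                suggestions.append(
                    FunctionSuggestion(
                        protein_id=p.protein_id,
                        suggested_product=product,
                        source_cluster=cid,
                        n_support=labels[product],
                    )
                )
    suggestions.sort(key=lambda s: s.protein_id)
    return suggestions


def marker_congruence(
    partition_a: Mapping[str, str],
    partition_b: Mapping[str, str],
    protein_to_phage: Mapping[str, str],
    marker_a: str = "marker_a",
    marker_b: str = "marker_b",
) -> CongruenceReport:
    """Adjusted Rand index between two marker clusterings, over shared phages.

    Each partition maps one marker's proteins to cluster ids; a phage may
    carry at most one protein per marker (two is an ambiguous mapping and an
    error).  With fewer than 3 shared phages the index is undefined and
    reported as None.
    """
    phage_cluster_a = _phage_clusters(partition_a, protein_to_phage, marker_a)
    phage_cluster_b = _phage_clusters(partition_b, protein_to_phage, marker_b)
    shared = sorted(set(phage_cluster_a) & set(phage_cluster_b))
    if len(shared) < 3:
        return CongruenceReport(marker_a, marker_b, len(shared), None)
    labels_a = [phage_cluster_a[ph] for ph in shared]
    labels_b = [phage_cluster_b[ph] for ph in shared]
    ari = float(adjusted_rand_score(labels_a, labels_b))
    return CongruenceReport(marker_a, marker_b, len(shared), ari)


def _phage_clusters(
    partition: Mapping[str, str], protein_to_phage: Mapping[str, str], marker: str
) -> dict[str, str]:
    out: dict[str, str] = {}
    for protein, cluster in partition.items():
        phage = protein_to_phage[protein]
        if phage in out:
            raise ValueError(f"phage {phage!r} has two proteins for marker {marker!r}")
        out[phage] = cluster
    return out


def scan_mtase_motif(protein: ProteinRecord) -> list[MtaseCall]:
    """Report every non-overlapping NPP[YFW] occurrence, left to right."""
    return [
        MtaseCall(
            protein_id=protein.protein_id,
            motif=m.group(0),
            motif_position=m.start() + 1,
        )
        for m in MTASE_MOTIF_RE.finditer(protein.sequence)
    ]


def replication_proximity(
    calls: Iterable[MtaseCall],
    features: Sequence[FeatureRecord],
    replication_keywords: Sequence[str] = DEFAULT_REPLICATION_KEYWORDS,
) -> list[MtaseCall]:
    """Annotate motif calls with the gene-ordinal distance to the replication module.

    Features must carry the CDS order of the prophage (sorted here by start
    coordinate); a CDS is a replication gene when its product contains any
    keyword (case-insensitive).  The distance is the minimal absolute
    difference in CDS ordinal positions, or None when the prophage has no
    replication-labelled gene.
    """
    cds = sorted((f for f in features if f.kind == "CDS"), key=lambda f: (f.start, f.end))
    ordinal: dict[str, int] = {}
    replication_ordinals: list[int] = []
    keywords = tuple(k.casefold() for k in replication_keywords)
    for i, f in enumerate(cds):
        pid = f.attributes.get("protein_id")
        if pid is not None:
            ordinal[pid] = i
        product = str(f.attributes.get("product", "")).casefold()
        if any(k in product for k in keywords):
            replication_ordinals.append(i)

    annotated: list[MtaseCall] = []
    for call in calls:
        distance = None
        if replication_ordinals and call.protein_id in ordinal:
            o = ordinal[call.protein_id]
            distance = min(abs(o - r) for r in replication_ordinals)
        annotated.append(
            MtaseCall(
                protein_id=call.protein_id,
                motif=call.motif,
                motif_position=call.motif_position,
                gene_distance_to_replication=distance,
            )
        )
    return annotated
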
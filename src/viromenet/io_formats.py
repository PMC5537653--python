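"""Readers and writers for the formats the pipeline touches.

Protein FASTA headers follow the convention ``>phageID|proteinID product...``:
the first whitespace-delimited token binds a protein to its parent (pro)phage,
the remainder of the description line is the product annotation.  Features
travel as GFF3 with 1-based inclusive coordinates, which are preserved
verbatim across read/write.  Networks are serialized either as a sorted TSV
edge list or as GraphML.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

HYPOTHETICAL_LABEL = "hypothetical protein"

#: header token ``phageID|proteinID``; configurable for other id dialects
DEFAULT_HEADER_RE = re.compile(r"^(?P<phage>[^|\s]+)\|(?P<protein>\S+)$")

#: feature kinds the pipeline understands; anything else is skipped on read
FEATURE_KINDS = frozenset({"CDS", "tRNA", "prophage_region"})


def is_hypothetical_label(product: str) -> bool:
    """Case-insensitive equality to ``hypothetical protein`` after whitespace collapse."""
    return " ".join(product.split()).casefold() == HYPOTHETICAL_LABEL


@dataclass
class ProteinRecord:
    """One phage-encoded protein."""

    protein_id: str
    phage_id: str
    product: str = HYPOTHETICAL_LABEL
    sequence: str = ""

    @property
    def is_hypothetical(self) -> bool:
        return is_hypothetical_label(self.product)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")


@dataclass
class FeatureRecord:
    """A genomic feature with 1-based inclusive coordinates."""

    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature on {self.replicon_id}: invalid coordinates "
                f"{self.start}..{self.end} (must satisfy 1 <= start <= end)"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_protein_fasta(path, header_re: re.Pattern = DEFAULT_HEADER_RE) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, order preserved.

    The id token must match ``header_re`` (default ``phageID|proteinID``);
    the rest of the description becomes the product label, defaulting to
    ``hypothetical protein`` when absent.  Duplicate protein ids and empty
    sequences are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = header_re.match(rec.id)
        if m is None:
            raise ValueError(
                f"{path}: header {rec.id!r} does not match the "
                "'phageID|proteinID' convention"
            )
        protein_id = m.group("protein")
        phage_id = m.group("phage")
        if protein_id in seen:
            raise ValueError(f"{path}: duplicate protein id {protein_id!r}")
        seen.add(protein_id)
        # description repeats the id token; the remainder is the product
        product = rec.description[len(rec.id):].strip() or HYPOTHETICAL_LABEL
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: protein {protein_id!r} has an empty sequence")
        records.append(ProteinRecord(protein_id, phage_id, product, seq))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records using the ``>phageID|proteinID product`` header dialect."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.phage_id}|{r.protein_id}",
            description=r.product,
        )
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_feature_table(path) -> list[FeatureRecord]:
    """Parse a GFF3 file into :class:`FeatureRecord` objects.

    Coordinates are kept 1-based inclusive exactly as in the file.  Feature
    types outside :data:`FEATURE_KINDS` are skipped with a logged warning;
    malformed or inverted coordinates are hard errors naming the line.
    """
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
                start, end = int(f.start), int(f.end)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line ({exc})") from exc
            if start > end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} > end {end}"
                )
            if f.featuretype not in FEATURE_KINDS:
                logger.warning("%s:%d: skipping feature of kind %r", path, lineno, f.featuretype)
                continue
            attributes = {k: v[0] if len(v) == 1 else list(v) for k, v in f.attributes.items()}
            features.append(
                FeatureRecord(
                    replicon_id=f.seqid,
                    start=start,
                    end=end,
                    strand=f.strand if f.strand in "+-" else "+",
                    kind=f.featuretype,
                    attributes=attributes,
                )
            )
    return features


def write_feature_table(features: Iterable[FeatureRecord], path) -> None:
    """Write features as GFF3 (coordinates unchanged, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attributes.items()))
            fh.write(
                "\t".join(
                    [
                        f.replicon_id,
                        "viromenet",
                        f.kind,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


EDGE_LIST_HEADER = "#protein_a\tprotein_b\tidentity\tcoverage\tevalue"


def write_network(net: nx.Graph, path, format: str = "edge_list") -> None:
    """Serialize a protein network.

    ``edge_list`` is a TSV with columns protein_a/protein_b/identity/coverage/
    evalue sorted lexicographically by (a, b) with a < b.  ``graphml`` carries
    the node attributes phage_id, product and degree.
    """
    if format == "edge_list":
        rows = []
        for a, b, data in net.edges(data=True):
            a, b = sorted((a, b))
            rows.append(
                (
                    a,
                    b,
                    f"{data.get('identity', 0.0):.2f}",
                    f"{data.get('coverage', 0.0):.2f}",
                    repr(data.get("evalue", 0.0)),
                )
            )
        rows.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w") as fh:
            fh.write(EDGE_LIST_HEADER + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
    elif format == "graphml":
        out = nx.Graph()
        for node in sorted(net.nodes):
            data = net.nodes[node]
            out.add_node(
                node,
                phage_id=data.get("phage_id", ""),
                product=data.get("product", ""),
                degree=net.degree[node],
            )
        for a, b, data in net.edges(data=True):
            out.add_edge(a, b, **{k: v for k, v in data.items()})
        nx.write_graphml(out, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_list(path) -> nx.Graph:
    """Read the TSV edge list produced by :func:`write_network` back into a graph."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b, identity, coverage, evalue = line.split("\t")
            g.add_edge(a, b, identity=float(identity), coverage=float(coverage), evalue=float(evalue))
    return g
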
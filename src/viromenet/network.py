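"""Reciprocated protein similarity network and its summary statistics.

An undirected edge (a, b) exists iff BOTH directed hits a->b and b->a pass
all three thresholds (E-value <= max, identity >= min, coverage >= min;
boundary values pass).  This "reciprocated similarity" rule is weaker than
reciprocal-best-hit: any pair whose similarity is mutually above threshold is
linked.  Isolated proteins remain graph members, so the node universe must
be supplied explicitly; the unit of protein grouping is the connected
component (subgraph).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import networkx as nx

from viromenet.io_formats import ProteinRecord
from viromenet.similarity_engine import SimilarityHit


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (68.05 -> 68.1), matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EdgeThresholds:
    """Edge admission thresholds; defaults are the standard 1e-5 / 50% / 50%."""

    evalue_max: float = 1e-5
    identity_min: float = 50.0
    coverage_min: float = 50.0

    def __post_init__(self) -> None:
        for name in ("identity_min", "coverage_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    def passes(self, hit: SimilarityHit) -> bool:
        return (
            hit.evalue <= self.evalue_max
            and hit.identity_pct >= self.identity_min
            and hit.query_coverage_pct >= self.coverage_min
        )


def build_network(
    hits: Iterable[SimilarityHit],
    thresholds: EdgeThresholds,
    proteins: Sequence[ProteinRecord],
) -> nx.Graph:
    """Build the reciprocated similarity network over an explicit node universe.

    Every protein becomes a node (with phage_id/product attributes) even if
    it gains no edge.  Edge attributes store the conservative combination of
    the two directed hits: min identity, min coverage, max E-value.
    """
    net = nx.Graph()
    for p in sorted(proteins, key=lambda p: p.protein_id):
        net.add_node(p.protein_id, phage_id=p.phage_id, product=p.product)

    passing: dict[tuple[str, str], SimilarityHit] = {}
    for hit in hits:
        if hit.query_id not in net or hit.subject_id not in net:
            unknown = hit.query_id if hit.query_id not in net else hit.subject_id
            raise ValueError(f"hit references unknown protein {unknown!r}")
        if hit.query_id == hit.subject_id:
            continue
        if thresholds.passes(hit):
            passing[(hit.query_id, hit.subject_id)] = hit

    for (q, s), fwd in passing.items():
        if q < s and (s, q) in passing:
            rev = passing[(s, q)]
            net.add_edge(
                q,
                s,
                identity=min(fwd.identity_pct, rev.identity_pct),
                coverage=min(fwd.query_coverage_pct, rev.query_coverage_pct),
                evalue=max(fwd.evalue, rev.evalue),
            )
    return net


def connected_components(net: nx.Graph) -> dict[str, str]:
    """Partition the network into connected components.

    Returns a node -> component-id map; the component id is its
    lexicographically smallest member, which makes the labelling
    deterministic under any node insertion order.
    """
    partition: dict[str, str] = {}
    for comp in nx.connected_components(net):
        cid = min(comp)
        for node in comp:
            partition[node] = cid
    return partition


@dataclass
class ClusterSummary:
    """Census of a clustered protein network."""

    n_nodes: int
    n_edges: int
    size_distribution: list[tuple[int, int]]  # (size s, count n), s descending
    n_multi_subgraphs: int
    n_singletons: int
    n_clustered_nodes: int
    pct_clustered: float

    @property
    def distribution_string(self) -> str:
        return render_distribution(self.size_distribution)


def summarize(partition: Mapping[str, str], net: nx.Graph) -> ClusterSummary:
    """Summary statistics of the component partition.

    A "subgraph" is a component with >= 2 nodes; its members are the
    clustered nodes.  pct_clustered is rendered half-up to one decimal for
    comparability with printed tables.
    """
    if set(partition) != set(net.nodes):
        raise ValueError("partition does not cover exactly the network's nodes")
    sizes: dict[str, int] = {}
    for node, cid in partition.items():
        sizes[cid] = sizes.get(cid, 0) + 1
    multi = [s for s in sizes.values() if s >= 2]
    n_singletons = sum(1 for s in sizes.values() if s == 1)
    n_clustered = sum(multi)
    dist_counts: dict[int, int] = {}
    for s in multi:
        dist_counts[s] = dist_counts.get(s, 0) + 1
    distribution = sorted(dist_counts.items(), key=lambda t: -t[0])
    n_nodes = net.number_of_nodes()
    pct = round_half_up(100.0 * n_clustered / n_nodes, 1) if n_nodes else 0.0
    return ClusterSummary(
        n_nodes=n_nodes,
        n_edges=net.number_of_edges(),
        size_distribution=distribution,
        n_multi_subgraphs=len(multi),
        n_singletons=n_singletons,
        n_clustered_nodes=n_clustered,
        pct_clustered=pct,
    )


_DIST_TOKEN = re.compile(r"^(\d+)s:(\d+)n$")


def render_distribution(distribution: Sequence[tuple[int, int]]) -> str:
    """Render a size distribution as ``"12s:6n, 11s:2n, ..."``, sizes descending."""
    ordered = sorted(distribution, key=lambda t: -t[0])
    return ", ".join(f"{s}s:{n}n" for s, n in ordered)


def parse_distribution(text: str) -> list[tuple[int, int]]:
    """Parse a ``"<s>s:<n>n"`` comma-joined distribution string (inverse of render)."""
    text = text.strip()
    if not text:
        return []
    pairs: list[tuple[int, int]] = []
    for token in text.split(","):
        token = token.strip()
        m = _DIST_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed distribution token {token!r}")
        pairs.append((int(m.group(1)), int(m.group(2))))
    return pairs


def summary_from_distribution(
    distribution: Sequence[tuple[int, int]], n_singletons: int, n_edges: int = 0
) -> ClusterSummary:
    """Build a :class:`ClusterSummary` from a printed size distribution.

    Lets published subgraph censuses be re-analysed without the underlying
    graph (the per-component sizes determine every count except n_edges,
    which is passed through).
    """
    n_clustered = sum(s * n for s, n in distribution)
    n_multi = sum(n for _, n in distribution)
    n_nodes = n_clustered + n_singletons
    pct = round_half_up(100.0 * n_clustered / n_nodes, 1) if n_nodes else 0.0
    return ClusterSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        size_distribution=sorted(distribution, key=lambda t: -t[0]),
        n_multi_subgraphs=n_multi,
        n_singletons=n_singletons,
        n_clustered_nodes=n_clustered,
        pct_clustered=pct,
    )
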
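"""Independent oracles used by the test suite.

These deliberately avoid the library paths used by the implementation:
the alignment oracle is a plain-Python exhaustive dynamic program, the
component oracle is an iterative depth-first search over an adjacency map,
and the coding-density oracle is a per-base bitmap.
"""

from __future__ import annotations


def sw_affine_score(query: str, subject: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal affine-gap Smith-Waterman score by exhaustive DP.

    A gap of length k costs gap_open + k * gap_extend.  Three-state
    (match / gap-in-query / gap-in-subject) recurrence, local: every cell
    floors at 0 and the optimum is the best cell anywhere.
    """
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (subject consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (query consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            sub = matrix[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def dfs_components(nodes, edges) -> set[frozenset]:
    """Connected components by explicit depth-first search."""
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen: set = set()
    components: set[frozenset] = set()
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.add(frozenset(comp))
    return components


def bitmap_coding_density(intervals, region_start: int, region_end: int) -> float:
    """Coding density % via a per-base coverage bitmap (overlaps counted once)."""
    length = region_end - region_start + 1
    bitmap = [False] * length
    for s, e in intervals:
        s, e = max(s, region_start), min(e, region_end)
        for pos in range(s, e + 1):
            bitmap[pos - region_start] = True
    return 100.0 * sum(bitmap) / length


def reciprocated_edges(hits, evalue_max: float, identity_min: float, coverage_min: float) -> set:
    """Double-loop filter over a directed hit table (edge-rule oracle)."""
    passing = {
        (h.query_id, h.subject_id)
        for h in hits
        if h.evalue <= evalue_max
        and h.identity_pct >= identity_min
        and h.query_coverage_pct >= coverage_min
    }
    return {
        frozenset((q, s))
        for (q, s) in passing
        if q != s and (s, q) in passing
    }
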
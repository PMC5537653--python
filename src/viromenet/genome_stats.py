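"""Per-prophage genome statistics: length, GC content, gene counts, coding density.

Lengths follow the 1-based inclusive convention (end - start + 1), the
GenBank standard.  GC content excludes N from the denominator.  Coding
density deduplicates overlapping CDS spans (each base counted once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from viromenet.io_formats import FeatureRecord
from viromenet.network import round_half_up

logger = logging.getLogger(__name__)


@dataclass
class ProphageSummaryRow:
    name: str
    replicon_id: str
    start: int
    end: int
    size_bp: int
    n_genes: int
    gc_pct: Optional[float]
    coding_density_pct: float
    integration_site: str = ""


def region_length(start: int, end: int) -> int:
    """Inclusive length of a 1-based region (2834796..2878945 -> 44150)."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def gc_content(sequence: str) -> Optional[float]:
    """GC percentage over A/C/G/T (N excluded); None for an all-N sequence.

    Invariant under reverse complement.  Display rounding is the caller's
    concern; use :func:`viromenet.network.round_half_up` at 2 decimals to
    match printed tables.
    """
    seq = sequence.upper()
    counts = {c: seq.count(c) for c in "ACGTN"}
    known = len(seq) - counts["N"]
    if known != sum(counts[c] for c in "ACGT"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    if known == 0:
        logger.warning("gc_content undefined: sequence is all N")
        return None
    return 100.0 * (counts["G"] + counts["C"]) / known


def coding_stats(
    features: Sequence[FeatureRecord], region_start: int, region_end: int
) -> tuple[int, float]:
    """(CDS count, coding density %) for CDS features inside a region.

    Density is the union of CDS spans (clipped to the region, overlaps
    counted once) over the region length.
    """
    length = region_length(region_start, region_end)
    intervals = []
    n_genes = 0
    for f in features:
        if f.kind != "CDS":
            continue
        s, e = max(f.start, region_start), min(f.end, region_end)
        if s > e:
            continue
        n_genes += 1
        intervals.append((s, e))
    intervals.sort()
    covered = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return n_genes, 100.0 * covered / length


def summarize_region(
    name: str,
    replicon_id: str,
    sequence: str,
    start: int,
    end: int,
    features: Sequence[FeatureRecord],
    integration_site: str = "",
) -> ProphageSummaryRow:
    """Table-style summary row for one prophage region."""
    region_seq = sequence[start - 1 : end]
    gc = gc_content(region_seq)
    n_genes, density = coding_stats(features, start, end)
    return ProphageSummaryRow(
        name=name,
        replicon_id=replicon_id,
        start=start,
        end=end,
        size_bp=region_length(start, end),
        n_genes=n_genes,
        gc_pct=round_half_up(gc, 2) if gc is not None else None,
        coding_density_pct=round_half_up(density, 1),
        integration_site=integration_site,
    )


def write_summary_table(rows: Sequence[ProphageSummaryRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#name\treplicon\tcoordinates\tsize_bp\tn_genes\tgc_pct\t"
            "coding_density_pct\tintegration_site\n"
        )
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        r.replicon_id,
                        f"{r.start}..{r.end}",
                        str(r.size_bp),
                        str(r.n_genes),
                        "NA" if r.gc_pct is None else f"{r.gc_pct:.2f}",
                        f"{r.coding_density_pct:.1f}",
                        r.integration_site,
                    ]
                )
                + "\n"
            )
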
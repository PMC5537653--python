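"""Prophage attachment-site (attL/attR) direct-repeat detection.

Site-specific integration of a temperate phage into a tRNA gene duplicates
the shared core of the attachment site: the first N nucleotides of the
integrated prophage (attL, overlapping the 3' end of the tRNA so that an
intact tRNA copy is reconstituted) recur as an exact direct repeat shortly
downstream of the prophage region (attR).  The detector is prefix-anchored:
it searches for the longest prefix of the region that recurs exactly, on the
forward strand, within a bounded window downstream of the region end.
Mismatched or inverted repeats are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from viromenet.io_formats import FeatureRecord

logger = logging.getLogger(__name__)


@dataclass
class ProphageRegion:
    """A prophage's 1-based inclusive placement on a host replicon."""

    replicon_id: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.name or self.replicon_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AttSite:
    """A detected direct repeat flanking a prophage (1-based inclusive bounds)."""

    repeat_length: int
    attL_start: int
    attL_end: int
    attR_start: int
    attR_end: int
    repeat_sequence: str
    anchor_trna: Optional[FeatureRecord] = None

    def __post_init__(self) -> None:
        la = self.attL_end - self.attL_start + 1
        lb = self.attR_end - self.attR_start + 1
        if not (la == lb == self.repeat_length == len(self.repeat_sequence)):
            raise ValueError("inconsistent att repeat lengths")


def find_att_repeat(
    replicon: str,
    region: ProphageRegion,
    max_prefix: int = 200,
    window: int = 1000,
    min_len: int = 10,
) -> Optional[AttSite]:
    """Longest exact downstream recurrence of the region's prefix, or None.

    Returns the maximal L <= max_prefix such that the first L nt of the
    region occur (forward strand, exact match) within ``window`` bp past the
    region end; among tied downstream positions the one nearest the region
    end wins.  None when the best L < min_len.  attL always sits at the
    region's 5' boundary.
    """
    if region.length < min_len:
        raise ValueError(
            f"region {region.name or region.replicon_id} shorter than min_len={min_len}"
        )
    prefix = replicon[region.start - 1 : region.start - 1 + min(max_prefix, region.length)]
    win_end = region.end + window
    if win_end > len(replicon):
        logger.warning(
            "search window truncated at replicon end (%d > %d)", win_end, len(replicon)
        )
        win_end = len(replicon)
    search = replicon[region.end : win_end]
    if len(search) < min_len:
        return None

    # occurrence of prefix[:L] is monotone decreasing in L -> binary search
    if search.find(prefix[:min_len]) < 0:
        return None
    lo, hi = min_len, len(prefix)  # lo always occurs
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if search.find(prefix[:mid]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    best_len = lo
    offset = search.find(prefix[:best_len])  # leftmost = nearest to region end
    att_r_start = region.end + offset + 1
    return AttSite(
        repeat_length=best_len,
        attL_start=region.start,
        attL_end=region.start + best_len - 1,
        attR_start=att_r_start,
        attR_end=att_r_start + best_len - 1,
        repeat_sequence=prefix[:best_len],
    )


def check_trna_reconstitution(att: AttSite, features: Sequence[FeatureRecord]) -> bool:
    """True iff a tRNA feature overlaps attL or attR by >= 1 bp.

    The overlapping tRNA (the integration anchor whose intact copy is
    reconstituted by integration) is recorded on ``att.anchor_trna``.
    """
    for f in features:
        if f.kind != "tRNA":
            continue
        if _overlaps(f.start, f.end, att.attL_start, att.attL_end) or _overlaps(
            f.start, f.end, att.attR_start, att.attR_end
        ):
            att.anchor_trna = f
            return True
    return False


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def write_att_table(sites, path, replicon_id: str) -> None:
    """BED-like TSV of att sites, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("#replicon\tattL_start\tattL_end\tattR_start\tattR_end\tlength\tanchor_trna\n")
        for att in sites:
            anchor = ""
            if att.anchor_trna is not None:
                anchor = str(att.anchor_trna.attributes.get("trna_isotype", "tRNA"))
            fh.write(
                "\t".join(
                    [
                        replicon_id,
                        str(att.attL_start),
                        str(att.attL_end),
                        str(att.attR_start),
                        str(att.attR_end),
                        str(att.repeat_length),
                        anchor,
                    ]
                )
                + "\n"
            )
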
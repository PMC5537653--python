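"""All-vs-all protein comparison by Smith-Waterman local alignment.

This module is the in-package stand-in for a BLASTP-style search step: each
ordered protein pair gets a directed hit with raw/bit score, E-value, percent
identity and query coverage.  Alignment uses optimal affine-gap Smith-Waterman
(BLOSUM62, gap open 11 / extend 1 by default, i.e. a gap of length k costs
11 + k), so there is no heuristic seeding, no composition-based statistics
and no edge-effect correction; absolute E-values therefore differ from NCBI
BLAST even though the score model is the same.

E-values follow the Karlin-Altschul formulation with the standard gapped
BLOSUM62 constants: bit = (lambda*S - ln K)/ln 2 and E = m*n*2^-bit with m
the query length and n the subject length (or the whole-database residue
count when ``db_wide_evalue`` is requested).

Identity uses the BLAST ``pident`` convention: identical aligned residue
pairs divided by all alignment columns, gap columns included.  Coverage is
the aligned query span over the query length, computed on the single optimal
local alignment (one trace has one HSP; this deliberately differs from
BLAST's multi-HSP ``qcovs``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

from Bio.Align import PairwiseAligner, substitution_matrices

#: residues accepted on input; X scores via the matrix's X column
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants.

    ``gap_open``/``gap_extend`` use the BLAST convention: a gap of length k
    costs ``gap_open + k * gap_extend``.  ``lam`` (nats) and ``k`` are the
    gapped Karlin-Altschul parameters for the default BLOSUM62 11/1 scheme.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw_score))


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # first gap residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class SimilarityHit:
    """One directed query -> subject comparison.

    Coordinates are 1-based inclusive bounds of the optimal local alignment;
    an empty alignment (no positively scoring pair) is encoded with raw_score
    0 and all bounds 0.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_pct: float
    query_coverage_pct: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    @property
    def is_empty(self) -> bool:
        return self.raw_score <= 0


def _validate(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    for i, c in enumerate(seq):
        if c not in PROTEIN_ALPHABET:
            raise ValueError(f"{which} sequence: non-alphabet character {c!r} at position {i + 1}")


# co-optimal traces examined for the deterministic tie-break
_TIEBREAK_LIMIT = 32


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    subject_id: str = "subject",
    database_residues: Optional[int] = None,
) -> SimilarityHit:
    """Optimal affine-gap Smith-Waterman local alignment of two proteins.

    Among co-optimal traces, the alignment with the smallest (q_start,
    s_start) is reported (examined up to a fixed number of traces, which
    covers all realistic tie patterns).  ``database_residues`` overrides the
    subject length n in the E-value search space for database-wide
    statistics.
    """
    _validate(query, "query")
    _validate(subject, "subject")
    aligner = _aligner(scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    alignments = aligner.align(query, subject)
    n = database_residues if database_residues is not None else len(subject)
    score = int(alignments.score) if alignments.score else 0
    if score <= 0:
        # no residue pair scores positively: minimal/empty local alignment
        return SimilarityHit(
            query_id,
            subject_id,
            raw_score=0,
            bit_score=scoring.bit_score(0),
            evalue=scoring.evalue(0, len(query), n),
            identity_pct=0.0,
            query_coverage_pct=0.0,
        )

    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        if i >= _TIEBREAK_LIMIT:
            break
        qb, sb = aln.aligned
        key = (int(qb[0][0]), int(sb[0][0]))
        if best_key is None or key < best_key:
            best, best_key = aln, key
    qb, sb = best.aligned

    identities = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qb, sb):
        for off in range(qe - qs):
            if query[qs + off] == subject[ss + off]:
                identities += 1
        columns += qe - qs
    for i in range(1, len(qb)):
        columns += int(qb[i][0] - qb[i - 1][1]) + int(sb[i][0] - sb[i - 1][1])

    q_start, q_end = int(qb[0][0]) + 1, int(qb[-1][1])
    s_start, s_end = int(sb[0][0]) + 1, int(sb[-1][1])
    return SimilarityHit(
        query_id,
        subject_id,
        raw_score=score,
        bit_score=scoring.bit_score(score),
        evalue=scoring.evalue(score, len(query), n),
        identity_pct=100.0 * identities / columns,
        query_coverage_pct=100.0 * (q_end - q_start + 1) / len(query),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


def all_vs_all(
    proteins,
    scoring: ScoringScheme = ScoringScheme(),
    score_floor: Optional[int] = None,
    db_wide_evalue: bool = False,
) -> list["SimilarityHit"]:
    """Directed hits for every ordered pair of distinct proteins.

    The optimal local alignment is computed once per unordered pair (raw
    score and identity are symmetric for a symmetric matrix) and reported in
    both directions with direction-specific coverage and bounds.  Output is
    sorted by (query_id, subject_id).  ``score_floor`` optionally drops hits
    with raw score strictly below the floor; callers must keep the floor
    permissive enough never to drop threshold-passing pairs.
    """
    records = list(proteins)
    if len(records) < 2:
        raise ValueError("all_vs_all needs at least 2 proteins")
    ids = [p.protein_id for p in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")

    total_residues = sum(len(p.sequence) for p in records)
    hits: list[SimilarityHit] = []
    ordered = sorted(records, key=lambda p: p.protein_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            n_a = total_residues if db_wide_evalue else None
            fwd = local_align(
                a.sequence, b.sequence, scoring, a.protein_id, b.protein_id,
                database_residues=n_a,
            )
            rev = _reverse_hit(fwd, a, b, scoring, total_residues if db_wide_evalue else None)
            for h in (fwd, rev):
                if score_floor is None or h.raw_score >= score_floor:
                    hits.append(h)
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def _reverse_hit(fwd: SimilarityHit, a, b, scoring: ScoringScheme, database_residues) -> SimilarityHit:
    """Directed b -> a hit derived from the a -> b optimal alignment."""
    n = database_residues if database_residues is not None else len(a.sequence)
    if fwd.is_empty:
        cov = 0.0
    else:
        cov = 100.0 * (fwd.s_end - fwd.s_start + 1) / len(b.sequence)
    return SimilarityHit(
        query_id=b.protein_id,
        subject_id=a.protein_id,
        raw_score=fwd.raw_score,
        bit_score=fwd.bit_score,
        evalue=scoring.evalue(fwd.raw_score, len(b.sequence), n),
        identity_pct=fwd.identity_pct,
        query_coverage_pct=cov,
        q_start=fwd.s_start,
        q_end=fwd.s_end,
        s_start=fwd.q_start,
        s_end=fwd.q_end,
    )


HIT_TABLE_HEADER = (
    "#qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tqstart\tqend\tsstart\tsend\tqcov"
)


def write_hit_table(hits: Iterable[SimilarityHit], path) -> None:
    """BLAST outfmt-6-like TSV of directed hits."""
    with open(path, "w") as fh:
        fh.write(HIT_TABLE_HEADER + "\n")
        for h in hits:
            length = h.q_end - h.q_start + 1 if not h.is_empty else 0
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(length),
                        repr(h.evalue),
                        f"{h.bit_score:.1f}",
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.query_coverage_pct:.2f}",
                    ]
                )
                + "\n"
            )
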
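# Methods

## Pairwise comparison model

Protein pairs are compared by optimal Smith–Waterman local alignment with
affine gaps (Gotoh recurrence, via Biopython's `PairwiseAligner`).
Defaults follow the conventional protein-search parameterization:
BLOSUM62, gap open 11, gap extend 1 (a gap of length k costs 11 + k).
There is no heuristic seeding, no composition-based score adjustment and no
edge-effect correction, so raw scores are exact optima and E-values are the
plain Karlin–Altschul estimate

    bit = (λ·S − ln K) / ln 2,      E = m·n·2^(−bit)

with λ = 0.267 nats and K = 0.041 (the standard gapped BLOSUM62 11/1
constants), m the query length and n the subject length — or the total
residue count of the dataset when database-wide statistics are requested
(`--db-wide-evalue`). Absolute E-values therefore differ from NCBI BLAST;
what matters for the pipeline is the thresholding behaviour, which is
stable across both conventions for the strong (≥50% identity, ≥50%
coverage) hits that form edges.

Percent identity is identical aligned residue pairs over all alignment
columns including gap columns (`pident` convention). Query coverage is the
aligned query span over the query length, measured on the single optimal
local alignment: one trace has one HSP, so this deliberately diverges from
BLAST's multi-HSP `qcovs`. Among co-optimal traces the alignment with the
smallest (q_start, s_start) is reported, making output deterministic.
A pair with no positively scoring residue pair yields an "empty" hit (raw
score 0, zero identity/coverage) that can never form an edge.

## Network model

The graph has one node per protein — including proteins that gain no edge,
so the node universe is passed explicitly — and an undirected edge (a, b)
exactly when the directed hits a→b **and** b→a each satisfy E ≤ 1e−5,
identity ≥ 50% and coverage ≥ 50% (boundary values pass; all three
thresholds configurable). "Reciprocated" means mutually above threshold,
not reciprocal-best-hit: requiring best hits would suppress the large
many-member families that are the object of study. Requiring both
directions makes the coverage criterion symmetric in effect: a short
protein embedded in a longer one passes in one direction only and gains no
edge.

Clusters are connected components; component labels are the
lexicographically smallest member id, so partitions are deterministic under
any insertion order. The census of component sizes is rendered
`"<size>s:<count>n"` comma-joined in descending size, and the parser is the
exact inverse, which lets published censuses be ingested and re-analysed:
every derived statistic (clustered-node count, subgraph count, clustered
percentage, the forest bound n_edges ≥ n_clustered − n_components) is
recomputed from the distribution rather than trusted. Percentages are
rounded half-up to the printed precision (one or two decimals) for
comparability with published tables.

## Function transfer and congruence

A hypothetical protein in a component with at least one annotated member
receives the component's most frequent non-hypothetical product; ties break
lexicographically on the product string. This is the simplest deterministic
rule consistent with "clustered together with proteins of predicted
function"; it never overwrites an existing annotation, and all-hypothetical
components yield nothing. Because published analyses do not state their
transfer rule, counts of suggested functions are comparable only in order
of magnitude, not exactly.

Congruence between two marker clusterings (e.g. TerL vs major capsid
protein) is the adjusted Rand index over phages carrying both markers
(scikit-learn's pair-counting implementation), undefined below 3 shared
phages. Under the ARI's convention the all-in-one vs all-singletons
comparison scores 0, which we adopt for degenerate partitions. A phage
contributing two proteins to one marker is rejected as ambiguous.

## MTase motif scan and replication proximity

Amino-methyltransferases (m6A/m4C) carry the catalytic motif IV
tetrapeptide NPP(Y/W/F); the scanner reports every non-overlapping
occurrence of `NPP[YFW]` left to right. On random sequences the expected
hit rate is 3·20⁻⁴ ≈ 1.9×10⁻⁵ per site, so the motif alone is a usable
screen at phage-proteome scale. The biologically meaningful corroboration —
CcrM-mimicking phage MTases sit inside the replication module — is
quantified as the minimal absolute difference in CDS ordinal position
between the MTase gene and the nearest gene whose product matches a
replication keyword set (default: substring "replication",
case-insensitive, configurable); prophages with no replication-labelled
gene return an undefined distance rather than zero. 5mC MTases have no
comparable short protein motif and are out of scope.

## Attachment-site detection

Integration of a tRNA-targeting phage leaves the att core as an exact
direct repeat: the first N nucleotides of the prophage region (attL,
covering the 3′ end of the disrupted tRNA, whose intact copy is thereby
reconstituted) recur shortly downstream of the region (attR). The detector
is prefix-anchored — the repeat must start at the region's first base, per
the "first N nucleotides" signature — and exact-match, forward strand only.
It returns the **longest** L ≤ 200 such that the region's L-prefix occurs
within 1000 bp past the region end (nearest occurrence on ties), rejecting
L < 10. Because occurrence of a prefix is monotone in its length, the
search is a binary search over L on top of plain substring matching.
Defaults (max_prefix 200, window 1000, min_len 10) bracket observed repeat
lengths of 17 and 57 bp with wide margin; at min_len 10 the per-position
false-positive probability on random sequence is 4⁻¹⁰ ≈ 10⁻⁶, negligible
over a 1 kb window. tRNA reconstitution is declared when any tRNA feature
overlaps attL or attR by ≥ 1 bp.

## Genome statistics

Region length is end − start + 1 (1-based inclusive, the GenBank
convention). Published prophage tables mix conventions: most rows match the
inclusive length, a few match end − start or neither (two rows appear to
have swapped size cells); the divergent rows are recorded as flagged
discrepancies in `viromenet.reference` rather than silently corrected, and
the tests assert the split. GC content excludes N from the denominator and
is undefined (None) on all-N input; coding density deduplicates overlapping
CDS spans so each base counts once.

## Synthetic data

The generator is the test bed's ground truth, emulating the features the
pipeline keys on — not realistic phage biology:

* **Families** evolve from one random ancestor under a star topology with
  i.i.d. per-site substitutions and no indels (indel-free is the simplest
  model whose expected identity is analytically controllable). Per-branch
  substitution probability p = 1 − sqrt(t/100) gives expected pairwise
  identity (1−p)² + p²/19 ≈ t/100 between two members (the p²/19 term is
  convergent substitution, ≤ 0.5 points over the range used). Default
  planted identities for studies are 60/75/90%. A planted motif is stamped
  at a fixed relative position and shielded from mutation.
* **Label policy**: unlabelled proteins are "hypothetical protein" with
  probability 0.70 (the fraction typical of phage annotation), otherwise a
  uniform draw from a 16-label functional vocabulary.
* **Hosts** are i.i.d. nucleotide background at a target GC (default 62%,
  with the prophage generated 1.5 points lower, reproducing the usual
  prophage/host GC contrast). The prophage's gene features follow a module
  layout (integrase first, MTase adjacent to replication, lysis genes last).
  The att repeat is planted by copying the prophage's N-prefix once into
  the first kilobase of the downstream flank, forcing the following base to
  differ from the prophage's next base (so detected length is exactly N,
  no off-by-one) and verifying the repeat occurs exactly once in the
  window; collisions regenerate the flank deterministically with a bounded
  retry budget. A 76-nt tRNA ends exactly at attL's last base.

What passing tests show: the pipeline recovers planted families, repeats
and motifs exactly under this model. What they do not show: robustness to
indels, domain shuffling, fragmented genes, inexact (mutated) att cores, or
compositional bias — real-data phenomena outside the generator.

## Problem sizes and numerical choices

Test and acceptance studies use small proteomes (tens of proteins,
sequences 150–250 aa), prophages of 4–12 kb and tens of replicate seeds —
sizes at which exhaustive all-vs-all optimal alignment is fast while every
statistic of interest (recovery, determinism, census arithmetic) is already
exercised at full fidelity. All randomness flows through one
`numpy.random.Generator` seeded from the single user-facing seed; identical
configs are byte-identical on disk. Rounding for display is decimal
half-up; internal comparisons are unrounded.

## Known limitations

* Single-HSP coverage understates BLAST `qcovs` for proteins with repeated
  or shuffled domains.
* E-values are uncorrected Karlin–Altschul estimates; do not compare them
  numerically to NCBI BLAST output.
* The att detector only finds exact, forward-strand, prefix-anchored
  repeats; degraded att cores of old prophage remnants will be missed.
* Function transfer inherits whatever annotation noise the labelled
  neighbours carry; it suggests, it does not validate.
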
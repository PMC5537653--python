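"""Seeded synthetic proteomes and host genomes with planted prophages.

Every downstream stage of the pipeline is exercised against data with known
ground truth:

* **Protein families** evolve from a random ancestor under a star topology
  with i.i.d. per-site substitution and no indels.  The per-branch
  substitution probability is p = 1 - sqrt(t/100) for a target pairwise
  identity of t percent, so two branches agree at a site with probability
  (1-p)^2 ~ t/100 (plus a small convergent-substitution term p^2/19).
  An optional amino-acid motif (e.g. the amino-MTase catalytic tetrapeptide
  NPPY) is stamped ungapped at a fixed relative position in every member
  and shielded from mutation.
* **Datasets** add unrelated singleton proteins, apply a product-label
  policy in which ~70% of unlabelled proteins are "hypothetical protein"
  (mirroring typical phage annotation), and record every protein's family
  in a truth map.
* **Host replicons** embed a prophage whose gene features follow a given
  module order (integrase first; MTase genes adjacent to the replication
  genes), flanked by an exact direct repeat: the first N nt of the prophage
  recur exactly once within 1 kb downstream of the region end, and a tRNA
  gene's 3' portion coincides with the attL repeat so that integration
  reconstitutes an intact tRNA copy.

All randomness flows through one ``numpy.random.Generator``; identical
configs (same seed) produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from viromenet.att_detector import AttSite
from viromenet.io_formats import (
    HYPOTHETICAL_LABEL,
    FeatureRecord,
    ProteinRecord,
    write_feature_table,
    write_protein_fasta,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: functional product vocabulary used when the label policy draws a function
FUNCTIONAL_LABELS = (
    "integrase",
    "CI repressor",
    "Cro-like protein",
    "replication initiation protein",
    "adenine-specific DNA methyltransferase",
    "terminase small subunit",
    "terminase large subunit",
    "portal protein",
    "head maturation protease",
    "major capsid protein",
    "major tail protein",
    "tail tape measure protein",
    "tail fiber protein",
    "holin",
    "endolysin",
    "ATP-dependent DNA ligase",
)

#: canonical prophage module order: integrase at the left end, the MTase
#: inside the replication module, lysis genes at the right
DEFAULT_GENE_LAYOUT = (
    "integrase",
    "CI repressor",
    "Cro-like protein",
    "adenine-specific DNA methyltransferase",
    "replication initiation protein",
    "terminase small subunit",
    "terminase large subunit",
    "portal protein",
    "major capsid protein",
    "major tail protein",
    "tail tape measure protein",
    "holin",
    "endolysin",
)


@dataclass(frozen=True)
class FamilySpec:
    """A homologous protein family spanning several phages."""

    family_id: str
    member_phages: tuple[str, ...]
    ancestor_length: int = 200
    target_identity: float = 75.0
    product_label: Optional[str] = None  # None -> per-protein label policy
    plant_motif: Optional[str] = None
    motif_rel_pos: float = 0.5  # relative position of the planted motif

    @property
    def n_members(self) -> int:
        return len(self.member_phages)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("family needs at least one member phage")
        if not (0.0 < self.target_identity <= 100.0):
            raise ValueError(f"target_identity must be in (0, 100], got {self.target_identity}")
        if self.plant_motif is not None and len(self.plant_motif) >= self.ancestor_length:
            raise ValueError("motif longer than ancestor")


@dataclass(frozen=True)
class ProphagePlantSpec:
    """Layout of one prophage to integrate into a synthetic host replicon."""

    name: str = "phiSynth1"
    prophage_length: int = 40_000
    att_repeat_length: int = 17
    trna_isotype: str = "tRNA-Phe(GAA)"
    gene_layout: tuple[str, ...] = DEFAULT_GENE_LAYOUT

    def __post_init__(self) -> None:
        if self.att_repeat_length < 0:
            raise ValueError("att_repeat_length must be >= 0")
        if self.att_repeat_length >= self.prophage_length:
            raise ValueError("att repeat must be shorter than the prophage")
        if self.gene_layout and self.gene_layout[0] != "integrase":
            raise ValueError("gene layout must start with the integrase")


@dataclass(frozen=True)
class SynthConfig:
    """One seeded synthetic study: families + singletons + planted prophages."""

    seed: int = 0
    families: tuple[FamilySpec, ...] = ()
    n_singletons: int = 0
    prophages: tuple[ProphagePlantSpec, ...] = ()
    host_gc: float = 62.0
    hypothetical_fraction: float = 0.70
    singleton_length: tuple[int, int] = (120, 400)

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family_id in config")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def generate_family(spec: FamilySpec, rng: np.random.Generator) -> list[ProteinRecord]:
    """Evolve ``n_members`` sequences from one random ancestor (star topology).

    Substitutions are i.i.d. per site with per-branch probability
    p = 1 - sqrt(target_identity/100); a substituted site is redrawn
    uniformly from the 19 other residues.  A planted motif is stamped at the
    same position in every member and never mutated.
    """
    length = spec.ancestor_length
    ancestor = np.array(list(_random_protein(rng, length)))
    motif_span: range = range(0)
    if spec.plant_motif:
        pos = int(round(spec.motif_rel_pos * (length - len(spec.plant_motif))))
        motif_span = range(pos, pos + len(spec.plant_motif))
        ancestor[list(motif_span)] = list(spec.plant_motif)
    p = 1.0 - math.sqrt(spec.target_identity / 100.0)
    members: list[ProteinRecord] = []
    aa = np.array(list(AA20))
    for i, phage in enumerate(spec.member_phages):
        seq = ancestor.copy()
        mutate = rng.random(length) < p
        for idx in np.nonzero(mutate)[0]:
            if idx in motif_span:
                continue
            choices = aa[aa != seq[idx]]
            seq[idx] = rng.choice(choices)
        members.append(
            ProteinRecord(
                protein_id=f"{spec.family_id}_p{i:02d}",
                phage_id=phage,
                product=spec.product_label or HYPOTHETICAL_LABEL,
                sequence="".join(seq),
            )
        )
    return members


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], dict[str, Optional[str]]]:
    """Families plus unrelated singletons, with a complete truth map.

    Proteins whose family does not fix a product get the label policy: with
    probability ``hypothetical_fraction`` the hypothetical label, otherwise
    a uniformly drawn functional product.  The truth map sends each
    protein_id to its family_id, or None for singletons.
    """
    rng = np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    truth: dict[str, Optional[str]] = {}

    for spec in config.families:
        members = generate_family(spec, rng)
        if spec.product_label is None:
            members = [replace(m, product=_draw_label(rng, config)) for m in members]
        for m in members:
            proteins.append(m)
            truth[m.protein_id] = spec.family_id

    phage_pool = sorted({ph for f in config.families for ph in f.member_phages}) or ["phageS1"]
    lo, hi = config.singleton_length
    for i in range(config.n_singletons):
        length = int(rng.integers(lo, hi + 1))
        rec = ProteinRecord(
            protein_id=f"sing_p{i:03d}",
            phage_id=phage_pool[i % len(phage_pool)],
            product=_draw_label(rng, config),
            sequence=_random_protein(rng, length),
        )
        proteins.append(rec)
        truth[rec.protein_id] = None
    return proteins, truth


def _draw_label(rng: np.random.Generator, config: SynthConfig) -> str:
    if rng.random() < config.hypothetical_fraction:
        return HYPOTHETICAL_LABEL
    return str(rng.choice(list(FUNCTIONAL_LABELS)))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    g = gc / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    return "".join(rng.choice(list("AGCT"), size=length, p=p))


_ATT_RETRIES = 20


def generate_host_with_prophage(
    spec: ProphagePlantSpec,
    rng: np.random.Generator,
    host_gc: float = 62.0,
    flank: int = 2000,
) -> tuple[str, list[FeatureRecord], Optional[AttSite]]:
    """Host replicon with one integrated prophage and ground-truth att site.

    The replicon is left flank + prophage + right flank at ``host_gc``
    background (the prophage itself is generated ~1.5 GC points below the
    host, the usual prophage/host contrast).  When ``att_repeat_length`` > 0
    the first N nt of the prophage are copied once into the first kilobase
    of the right flank, made non-extendable (the base after the copy differs
    from the prophage's next base), and verified to occur exactly once in
    the downstream window; collisions trigger deterministic regeneration of
    the flank, bounded by a retry budget.  A 76-nt tRNA gene ends exactly at
    the attL repeat's last base, so its 3' portion is the repeat.
    """
    if flank < 1100:
        raise ValueError("right flank must cover the 1 kb att search window")
    L = spec.att_repeat_length
    prophage = _random_dna(rng, spec.prophage_length, max(host_gc - 1.5, 1.0))
    left = _random_dna(rng, flank, host_gc)
    region_start = flank + 1
    region_end = flank + spec.prophage_length

    att_truth: Optional[AttSite] = None
    if L > 0:
        repeat = prophage[:L]
        next_base = prophage[L]
        for attempt in range(_ATT_RETRIES):
            right = _random_dna(rng, flank, host_gc)
            offset = int(rng.integers(20, 1000 - L))  # 0-based offset into the right flank
            blocker = str(rng.choice([b for b in "ACGT" if b != next_base]))
            right = right[:offset] + repeat + blocker + right[offset + L + 1:]
            window = right[:1000]
            if window.count(repeat) == 1:
                break
        else:
            raise RuntimeError("could not plant a unique att repeat (retry budget exhausted)")
        att_r_start = region_end + offset + 1
        att_truth = AttSite(
            repeat_length=L,
            attL_start=region_start,
            attL_end=region_start + L - 1,
            attR_start=att_r_start,
            attR_end=att_r_start + L - 1,
            repeat_sequence=repeat,
        )
    else:
        right = _random_dna(rng, flank, host_gc)

    replicon = left + prophage + right
    replicon_id = f"{spec.name}_host"

    features: list[FeatureRecord] = [
        FeatureRecord(
            replicon_id=replicon_id,
            start=region_start,
            end=region_end,
            kind="prophage_region",
            attributes={"name": spec.name},
        )
    ]
    # tRNA whose 3' end coincides with the attL repeat end (att-less case:
    # the tRNA sits fully upstream of the prophage)
    trna_end = region_start + L - 1 if L > 0 else region_start - 1
    features.append(
        FeatureRecord(
            replicon_id=replicon_id,
            start=trna_end - 75,
            end=trna_end,
            kind="tRNA",
            attributes={"trna_isotype": spec.trna_isotype},
        )
    )
    features.extend(_layout_genes(spec, rng, replicon_id, region_start, region_end, L))
    if att_truth is not None:
        att_truth.anchor_trna = features[1]
    return replicon, features, att_truth


def _layout_genes(
    spec: ProphagePlantSpec,
    rng: np.random.Generator,
    replicon_id: str,
    region_start: int,
    region_end: int,
    att_len: int,
) -> list[FeatureRecord]:
    """CDS features in layout order, evenly packed inside the prophage region."""
    n = len(spec.gene_layout)
    if n == 0:
        return []
    usable = spec.prophage_length - att_len - 100
    gene_len = max(150, min(900, usable // max(n, 1) - 110))
    features: list[FeatureRecord] = []
    pos = region_start + att_len + 10
    for i, product in enumerate(spec.gene_layout):
        gap = int(rng.integers(20, 101))
        start = pos
        end = start + gene_len - 1
        if end > region_end:
            raise ValueError("gene layout does not fit inside the prophage region")
        features.append(
            FeatureRecord(
                replicon_id=replicon_id,
                start=start,
                end=end,
                kind="CDS",
                attributes={
                    "protein_id": f"{spec.name}_p{i + 1:02d}",
                    "product": product,
                },
            )
        )
        pos = end + 1 + gap
    return features


def write_dataset(config: SynthConfig, outdir) -> dict[str, Path]:
    """Materialize a config as FASTA + GFF3 + truth TSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, truth = generate_dataset(config)
    paths = {
        "proteins": outdir / "proteins.faa",
        "truth": outdir / "truth.tsv",
    }
    write_protein_fasta(proteins, paths["proteins"])
    with open(paths["truth"], "w") as fh:
        fh.write("#protein_id\tfamily_id\n")
        for pid in sorted(truth):
            fh.write(f"{pid}\t{truth[pid] or 'singleton'}\n")

    rng = np.random.default_rng(config.seed + 1)
    for i, spec in enumerate(config.prophages):
        replicon, features, att = generate_host_with_prophage(spec, rng, config.host_gc)
        fasta = outdir / f"host_{spec.name}.fna"
        gff = outdir / f"host_{spec.name}.gff3"
        with open(fasta, "w") as fh:
            fh.write(f">{features[0].replicon_id}\n")
            for j in range(0, len(replicon), 70):
                fh.write(replicon[j : j + 70] + "\n")
        write_feature_table(features, gff)
        paths[f"host_{spec.name}_fasta"] = fasta
        paths[f"host_{spec.name}_gff"] = gff
        att_path = outdir / f"host_{spec.name}.att_truth.tsv"
        with open(att_path, "w") as fh:
            fh.write("#attL_start\tattL_end\tattR_start\tattR_end\tlength\n")
            if att is not None:
                fh.write(
                    f"{att.attL_start}\t{att.attL_end}\t{att.attR_start}\t"
                    f"{att.attR_end}\t{att.repeat_length}\n"
                )
        paths[f"host_{spec.name}_att_truth"] = att_path
    return paths


def default_config(seed: int = 0) -> SynthConfig:
    """A small demonstration study: three families, decoys, one planted prophage."""
    return SynthConfig(
        seed=seed,
        families=(
            FamilySpec("famA", ("phage1", "phage2", "phage3"), 220, 90.0, "terminase large subunit"),
            FamilySpec("famB", ("phage1", "phage2", "phage3", "phage4"), 180, 75.0, "major capsid protein"),
            FamilySpec(
                "famC",
                ("phage2", "phage3", "phage4"),
                240,
                60.0,
                "adenine-specific DNA methyltransferase",
                plant_motif="NPPY",
            ),
        ),
        n_singletons=6,
        prophages=(ProphagePlantSpec(name="phiSynth1", prophage_length=12_000),),
    )
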
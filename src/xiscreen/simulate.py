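"""Synthetic inputs emulating a sexed small-RNA blastocyst study.

The generator builds everything the pipeline consumes:

* a toy genome (one autosome, an X, a small mitochondrial contig) with at
  least one feature of every ncRNA class, a repeat family copied to several
  loci (to exercise multi-mapping), tRNA intervals, and two X-linked mature
  miRNAs planted adjacent inside one host-gene interval — the arrangement of
  a clustered miRNA pair inside a host lncRNA intron;
* strain variants (two SNVs that create/destroy degenerate enzyme sites, one
  short-insertion polymorphism) for allelic assays;
* sexed read libraries: per-feature counts are Poisson at the model means,
  read lengths uniform on 18–26 nt, every read an exact genomic substring
  (forward or reverse complement). Paternally imprinted X-linked features
  yield exactly zero male reads, because males carry no paternal X — this is
  the ground truth the screen must recover. A degradation background is
  drawn from repeat/tRNA/random intervals; an optional unmappable fraction
  emulates reads that fail perfect-match mapping;
* F1 hybrid transcripts under a chosen imprinting mode, and lognormal-noise
  qPCR replicate ratios.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotationFeature,
    CrossDesign,
    GenomeRef,
    SmallRNARead,
    StrainVariant,
    revcomp,
)

_BASES = np.array(list("ACGT"))

MT_LENGTH = 4000
MIN_CHROM_LENGTH = 10_000


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@dataclass(frozen=True)
class FeatureExpression:
    """Expected read counts per sex for one feature."""

    mean_female: float
    mean_male: float
    imprint_mode: str = "none"  # paternal | maternal | none
    x_linked: bool = False

    def __post_init__(self) -> None:
        if self.mean_female < 0 or self.mean_male < 0:
            raise ValueError("means must be non-negative")
        if self.imprint_mode not in ("paternal", "maternal", "none"):
            raise ValueError(f"bad imprint_mode {self.imprint_mode!r}")
        # Males carry only a maternal X: a paternally imprinted X-linked
        # feature cannot produce male reads.
        if self.imprint_mode == "paternal" and self.x_linked and self.mean_male != 0:
            raise ValueError("paternal X-linked feature must have male mean 0")


@dataclass(frozen=True)
class ExpressionModel:
    """Per-feature expression means plus the degradation background.

    ``degradation_fraction`` is the expected share of the nominal library
    size drawn from repeat/tRNA/background intervals; ``degradation_mix``
    splits it into (repeat, tRNA, random background) proportions.
    """

    features: dict[str, FeatureExpression]
    degradation_fraction: float = 0.9
    degradation_mix: tuple[float, float, float] = (0.5, 0.2, 0.3)

    def __post_init__(self) -> None:
        if not (0.0 <= self.degradation_fraction <= 1.0):
            raise ValueError("degradation_fraction must be in [0, 1]")
        if abs(sum(self.degradation_mix) - 1.0) > 1e-9 or min(self.degradation_mix) < 0:
            raise ValueError("degradation_mix must be non-negative and sum to 1")


def make_toy_genome(
    seed: int, autosome_length: int = 50_000, x_length: int = 50_000
) -> tuple[GenomeRef, list[AnnotationFeature], list[StrainVariant]]:
    """Deterministic toy genome with annotations and strain variants.

    The X carries a host-gene interval (lincRNA) containing two adjacent
    hairpins, each with a mature miRNA — the planted paternally expressed
    cluster. A 200 nt repeat unit is copied to three autosomal and two
    X-linked loci so repeat-derived reads genuinely multi-map.
    """
    if autosome_length < MIN_CHROM_LENGTH or x_length < MIN_CHROM_LENGTH:
        raise ValueError(f"chromosome lengths must be >= {MIN_CHROM_LENGTH}")
    rng = np.random.default_rng(seed)
    chr2 = list(_random_seq(rng, autosome_length))
    chrx = list(_random_seq(rng, x_length))
    chrm = list(_random_seq(rng, MT_LENGTH))

    features: list[AnnotationFeature] = []

    def add(fid, cls, chrom, start, length, strand="+"):
        features.append(AnnotationFeature(fid, cls, chrom, start, start + length, strand))

    # autosomal ncRNA panel
    add("rRNA_1", "rRNA", "chr2", 500, 120)
    add("snRNA_1", "snRNA", "chr2", 900, 150, "-")
    add("snoRNA_1", "snoRNA", "chr2", 1300, 135)
    add("misc_1", "misc_RNA", "chr2", 1700, 200)
    add("linc_auto_1", "lincRNA", "chr2", 2100, 400, "-")
    add("mir_ctrl_hp", "miRNA_hairpin", "chr2", 2700, 80)
    add("mir_ctrl", "miRNA_mature", "chr2", 2710, 22)
    add("tRNA_1", "tRNA", "chr2", 3000, 72)
    add("tRNA_2", "tRNA", "chr2", 3200, 72, "-")

    # repeat family: one unit, copies on chr2 and chrX
    unit = _random_seq(rng, 200)
    repeat_pos = [
        ("chr2", int(autosome_length * 0.55)),
        ("chr2", int(autosome_length * 0.65)),
        ("chr2", int(autosome_length * 0.75)),
        ("chrX", int(x_length * 0.60)),
        ("chrX", int(x_length * 0.80)),
    ]
    for i, (chrom, pos) in enumerate(repeat_pos, 1):
        target = chr2 if chrom == "chr2" else chrx
        target[pos : pos + 200] = unit
        add(f"repeat_{i}", "repeat", chrom, pos, 200)

    # X-linked cluster: two mature miRNAs adjacent, inside hairpins, inside
    # one host-gene interval
    add("Ftx_like", "lincRNA", "chrX", 1000, 1200)
    add("mir374_hp", "miRNA_hairpin", "chrX", 1200, 80)
    add("mir374", "miRNA_mature", "chrX", 1220, 22)
    add("mir421_hp", "miRNA_hairpin", "chrX", 1300, 80)
    add("mir421", "miRNA_mature", "chrX", 1320, 23)

    # mitochondrial features
    add("mt_tRNA_1", "Mt_tRNA", "chrM", 200, 70)
    add("mt_rRNA_1", "Mt_rRNA", "chrM", 600, 950)

    # strain variants on chrX (reference genome carries the B6 allele)
    chrx[2500:2505] = "ACTGT"  # HpyCH4III site in B6; JF1 T destroys it
    chrx[3000:3006] = "CCAAAG"  # StyI site absent in B6; JF1 G creates CCWWGG
    chrx[3500:3507] = "GTAAACG"  # B6 triple-A run; JF1 has a double A
    x_str = "".join(chrx)
    variants = [
        StrainVariant(
            "ftx_snv", x_str[2441:2501], x_str[2502:2562], "C", "T", "SNV"
        ),
        StrainVariant(
            "jpx_snv", x_str[2944:3004], x_str[3005:3065], "A", "G", "SNV"
        ),
        StrainVariant(
            "zcchc13_ins", x_str[3442:3502], x_str[3505:3565], "AAA", "AA", "insertion"
        ),
    ]

    genome = GenomeRef(
        chromosomes={"chr2": "".join(chr2), "chrX": x_str, "chrM": "".join(chrm)},
        x_chrom="chrX",
        mt_chrom="chrM",
    )
    return genome, features, variants


def default_expression_model() -> ExpressionModel:
    """Study-design defaults for the toy genome's features.

    The planted paternal X-linked cluster uses the observed female read
    counts of the real screen's two candidate miRNAs (46 and 38) with male
    means fixed at zero; an abundant autosomal control miRNA dominates the
    ncRNA fraction; one autosomal snoRNA is female-biased and one snRNA
    male-biased to populate both fold-change lists; 90% of the nominal
    library is degradation background, of which 70% derives from repeat or
    tRNA intervals.
    """
    f = {
        "mir374": FeatureExpression(46, 0, "paternal", x_linked=True),
        "mir421": FeatureExpression(38, 0, "paternal", x_linked=True),
        "mir374_hp": FeatureExpression(3, 0, "paternal", x_linked=True),
        "mir421_hp": FeatureExpression(2, 0, "paternal", x_linked=True),
        "Ftx_like": FeatureExpression(15, 0, "paternal", x_linked=True),
        "mir_ctrl": FeatureExpression(300, 300),
        "mir_ctrl_hp": FeatureExpression(4, 4),
        "rRNA_1": FeatureExpression(30, 30),
        "snRNA_1": FeatureExpression(0.7, 70),
        "snoRNA_1": FeatureExpression(96, 0.8),
        "misc_1": FeatureExpression(10, 12),
        "linc_auto_1": FeatureExpression(12, 12),
        "mt_tRNA_1": FeatureExpression(80, 90),
        "mt_rRNA_1": FeatureExpression(40, 50),
    }
    return ExpressionModel(features=f)


def _sample_feature_read(
    rng: np.random.Generator, genome: GenomeRef, feat: AnnotationFeature
) -> str:
    max_len = min(26, feat.length)
    if max_len < 18:
        raise ValueError(f"feature {feat.feature_id!r} shorter than 18 nt")
    read_len = int(rng.integers(18, max_len + 1))
    start = feat.start + int(rng.integers(0, feat.length - read_len + 1))
    seq = genome.chromosomes[feat.chrom][start : start + read_len]
    return revcomp(seq) if feat.strand == "-" else seq


def _sample_background_read(
    rng: np.random.Generator,
    genome: GenomeRef,
    ncrna: dict[str, list[tuple[int, int]]],
) -> str:
    """A random intergenic read: background degradation by construction
    never overlaps an ncRNA interval (a fragment that did would have been
    cataloged as that ncRNA, not as background)."""
    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
    p = lengths / lengths.sum()
    while True:
        chrom = names[int(rng.choice(len(names), p=p))]
        seq = genome.chromosomes[chrom]
        read_len = int(rng.integers(18, 27))
        start = int(rng.integers(0, len(seq) - read_len + 1))
        end = start + read_len
        if any(start < e and s < end for s, e in ncrna.get(chrom, ())):
            continue
        out = seq[start:end]
        return revcomp(out) if rng.random() < 0.5 else out


def _occurs_in_genome(seq: str, genome: GenomeRef) -> bool:
    rc = revcomp(seq)
    return any(seq in c or rc in c for c in genome.chromosomes.values())


def simulate_libraries(
    genome: GenomeRef,
    annotations: Sequence[AnnotationFeature],
    model: ExpressionModel,
    n_reads_per_sex: int,
    seed: int,
    unmappable_fraction: float = 0.0,
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Simulate the female and male read libraries.

    Read ids encode their origin (``<S>_<feature>_<i>``, ``<S>_degr_<kind>_<i>``,
    ``<S>_unmappable_<i>``) so that ground truth stays recoverable in tests.
    """
    if n_reads_per_sex <= 0:
        raise ValueError("n_reads_per_sex must be positive")
    by_id = {f.feature_id: f for f in annotations}
    for fid in model.features:
        if fid not in by_id:
            raise ValueError(f"expression model references unknown feature {fid!r}")
    repeat_pool = [f for f in annotations if f.class_label == "repeat"]
    trna_pool = [f for f in annotations if f.class_label == "tRNA"]
    ncrna_spans: dict[str, list[tuple[int, int]]] = {}
    for f in annotations:
        if f.class_label not in ("repeat", "tRNA"):
            ncrna_spans.setdefault(f.chrom, []).append((f.start, f.end))

    rng = np.random.default_rng(seed)
    libraries: list[list[SmallRNARead]] = []
    for sex in ("female", "male"):
        tag = sex[0].upper()
        reads: list[SmallRNARead] = []
        for fid in sorted(model.features):
            expr = model.features[fid]
            mean = expr.mean_female if sex == "female" else expr.mean_male
            count = int(rng.poisson(mean)) if mean > 0 else 0
            feat = by_id[fid]
            for i in range(count):
                seq = _sample_feature_read(rng, genome, feat)
                reads.append(SmallRNARead(f"{tag}_{fid}_{i}", seq, sex))
        n_degr = int(rng.poisson(model.degradation_fraction * n_reads_per_sex))
        p_rep, p_trna, _ = model.degradation_mix
        for i in range(n_degr):
            u = rng.random()
            if u < p_rep and repeat_pool:
                feat = repeat_pool[int(rng.integers(0, len(repeat_pool)))]
                seq, kind = _sample_feature_read(rng, genome, feat), "repeat"
            elif u < p_rep + p_trna and trna_pool:
                feat = trna_pool[int(rng.integers(0, len(trna_pool)))]
                seq, kind = _sample_feature_read(rng, genome, feat), "tRNA"
            else:
                seq, kind = _sample_background_read(rng, genome, ncrna_spans), "background"
            reads.append(SmallRNARead(f"{tag}_degr_{kind}_{i}", seq, sex))
        if unmappable_fraction > 0:
            n_un = int(rng.poisson(unmappable_fraction * n_reads_per_sex))
            for i in range(n_un):
                while True:
                    seq = _random_seq(rng, int(rng.integers(18, 27)))
                    if not _occurs_in_genome(seq, genome):
                        break
                reads.append(SmallRNARead(f"{tag}_unmappable_{i}", seq, sex))
        libraries.append(reads)
    return libraries[0], libraries[1]


def simulate_f1_transcripts(
    cross: CrossDesign,
    variant: StrainVariant,
    imprint_mode: str,
    n: int,
    seed: int,
) -> list[str]:
    """Transcript (amplicon) sequences expressed in an F1 hybrid.

    Paternal mode emits only the paternal-X-haplotype allele, maternal the
    maternal one; mode "none" draws each transcript's allele 50:50.
    """
    if imprint_mode not in ("paternal", "maternal", "none"):
        raise ValueError(f"bad imprint_mode {imprint_mode!r}")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if imprint_mode == "paternal":
            strain = cross.paternal_x_haplotype
        elif imprint_mode == "maternal":
            strain = cross.maternal_x_haplotype
        else:
            strain = "B6" if rng.random() < 0.5 else "JF1"
        out.append(variant.amplicon(strain))
    return out


def simulate_qpcr(
    true_female_ratio: float,
    true_male_ratio: float,
    cv: float,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Replicate relative-expression ratios per sex with lognormal noise.

    The multiplicative noise term has unit mean and coefficient of variation
    ``cv`` (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2); cv = 0 reproduces the
    true ratios exactly.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if true_female_ratio < 0 or true_male_ratio < 0:
        raise ValueError("true ratios must be non-negative")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    for sex, true in (("female", true_female_ratio), ("male", true_male_ratio)):
        for rep in range(1, n_reps + 1):
            noise = 1.0 if cv == 0 else float(np.exp(rng.normal(-sigma * sigma / 2, sigma)))
            rows.append({"sex": sex, "replicate": rep, "value": true * noise})
    return pd.DataFrame(rows, columns=["sex", "replicate", "value"])
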
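"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere (BED convention). The ncRNA
class vocabulary is closed and kept in the row order of the classification
summary table; ``repeat`` and ``tRNA`` are secondary-pass labels applied only
to reads that matched no ncRNA class ("only genomic" reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: ncRNA classes, in summary-table row order.
RNA_CLASSES: tuple[str, ...] = (
    "miRNA_mature",
    "Mt_tRNA",
    "Mt_rRNA",
    "snRNA",
    "rRNA",
    "snoRNA",
    "misc_RNA",
    "lincRNA",
    "miRNA_hairpin",
)

#: Secondary-annotation classes for the "only genomic" fraction.
SECONDARY_CLASSES: tuple[str, ...] = ("repeat", "tRNA")

ALL_CLASSES: tuple[str, ...] = RNA_CLASSES + SECONDARY_CLASSES

STRAINS: tuple[str, ...] = ("B6", "JF1")

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_RC)[::-1]


def _check_dna(seq: str, what: str) -> None:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"{what} contains non-ACGT symbols: {bad}")


@dataclass(frozen=True)
class GenomeRef:
    """A reference genome: named chromosomes plus the identity of the X.

    ``mt_chrom`` names the mitochondrial contig when present (mitochondrial
    tRNA/rRNA features live there).
    """

    chromosomes: dict[str, str]
    x_chrom: str
    mt_chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        if self.x_chrom not in self.chromosomes:
            raise ValueError(f"x_chrom {self.x_chrom!r} not among chromosomes")
        if self.mt_chrom is not None and self.mt_chrom not in self.chromosomes:
            raise ValueError(f"mt_chrom {self.mt_chrom!r} not among chromosomes")
        for name, seq in self.chromosomes.items():
            _check_dna(seq, f"chromosome {name!r}")

    def __len__(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class AnnotationFeature:
    """A genomic interval carrying one RNA class label."""

    feature_id: str
    class_label: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ValueError(
                f"unknown class label {self.class_label!r} for {self.feature_id!r}"
            )
        if self.end <= self.start:
            raise ValueError(f"feature {self.feature_id!r}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SmallRNARead:
    """One sequenced small RNA (possibly collapsed to a multiplicity)."""

    read_id: str
    sequence: str
    library_sex: str  # "female" | "male"
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.library_sex not in ("female", "male"):
            raise ValueError(f"library_sex must be female/male, got {self.library_sex!r}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PerfectHit:
    """A perfect, full-length match of a read to the genome."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class StrainVariant:
    """A B6/JF1 polymorphism at an assayed locus.

    The reference genome carries the B6 allele; per-allele amplicons are
    ``flank5 + allele + flank3``.
    """

    locus: str
    flank5: str
    flank3: str
    b6_allele: str
    jf1_allele: str
    kind: str  # "SNV" | "insertion"

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "insertion"):
            raise ValueError(f"variant kind must be SNV or insertion, got {self.kind!r}")
        if self.b6_allele == self.jf1_allele:
            raise ValueError(f"variant {self.locus!r}: alleles identical")
        if self.kind == "insertion" and len(self.b6_allele) == len(self.jf1_allele):
            raise ValueError(f"insertion variant {self.locus!r}: alleles same length")
        for s in (self.flank5, self.flank3, self.b6_allele, self.jf1_allele):
            _check_dna(s, f"variant {self.locus!r}")

    def amplicon(self, strain: str) -> str:
        """Amplicon sequence for one strain's allele."""
        if strain == "B6":
            allele = self.b6_allele
        elif strain == "JF1":
            allele = self.jf1_allele
        else:
            raise ValueError(f"no allele defined for strain {strain!r}")
        return self.flank5 + allele + self.flank3


@dataclass(frozen=True)
class CrossDesign:
    """A mating scheme fixing the parental origin of each X haplotype.

    XY males inherit their single X from the mother, so the paternal X of
    the offspring is the father's (sole) X — for an F1 father of a JF1
    mother, that X is JF1 regardless of the father's autosomal makeup.
    """

    maternal_strain: str
    paternal_strain: str
    maternal_x_haplotype: str
    paternal_x_haplotype: str

    def __post_init__(self) -> None:
        for h in (self.maternal_x_haplotype, self.paternal_x_haplotype):
            if h not in STRAINS:
                raise ValueError(f"X haplotype must be one of {STRAINS}, got {h!r}")

    @property
    def informative(self) -> bool:
        return self.maternal_x_haplotype != self.paternal_x_haplotype


def cross_jf1_female_x_b6_male() -> CrossDesign:
    """(JF1 x B6) F1: JF1 mother, B6 father -> paternal X is B6."""
    return CrossDesign("JF1", "B6", maternal_x_haplotype="JF1", paternal_x_haplotype="B6")


def cross_b6_female_x_f1_male() -> CrossDesign:
    """(B6 x (JF1 x B6)) F1: B6 mother, F1 father whose X came from his JF1
    mother -> paternal X is JF1."""
    return CrossDesign("B6", "JF1xB6", maternal_x_haplotype="B6", paternal_x_haplotype="JF1")


def reciprocal_crosses() -> tuple[CrossDesign, CrossDesign]:
    """The standard reciprocal pair used for parent-of-origin inference."""
    return cross_jf1_female_x_b6_male(), cross_b6_female_x_f1_male()
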
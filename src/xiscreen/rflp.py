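"""In-silico allele-specific genotyping and parent-of-origin inference.

Allele discrimination uses either restriction-fragment-length polymorphism
(RFLP: a strain variant creates or destroys a degenerate enzyme recognition
site, so the two alleles' digests differ) or direct sequence matching across
a short insertion. Parent-of-origin is then inferred from reciprocal
crosses: because the two crosses swap which strain contributes the paternal
X, a genuinely imprinted locus shows the *opposite* strain allele in the two
crosses, while a strain-specific (cis-regulatory) effect shows the same
allele in both — the reciprocal design is what separates the two.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import CrossDesign, StrainVariant

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Default gel detection floor: fragments shorter than this are treated as
#: unobservable in RFLP genotyping.
DEFAULT_DETECTION_FLOOR = 10


@dataclass(frozen=True)
class EnzymeMotif:
    """A restriction enzyme recognition motif over the IUPAC alphabet.

    ``cut_offset`` is the cut position within the site, defaulting to the
    end of the recognition sequence. Genotype calls rest on presence/absence
    of cutting, not absolute fragment sizes, so they are offset-invariant.
    """

    name: str
    recognition: str
    cut_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition sequence must be >= 4 nt")
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in motif: {sorted(bad)}")

    @property
    def cut(self) -> int:
        return len(self.recognition) if self.cut_offset is None else self.cut_offset

    def regex(self) -> re.Pattern[str]:
        pattern = "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in self.recognition
        )
        return re.compile("(?=" + pattern + ")")


#: Built-in enzymes. Both recognition sites are their own reverse
#: complements, so a single-strand scan finds every site.
BUILTIN_ENZYMES: dict[str, EnzymeMotif] = {
    "HpyCH4III": EnzymeMotif("HpyCH4III", "ACNGT"),
    "StyI": EnzymeMotif("StyI", "CCWWGG"),
}


def find_sites(sequence: str, motif: EnzymeMotif) -> list[int]:
    """All start positions where the degenerate motif matches (overlaps allowed)."""
    if not set(sequence) <= set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    return [m.start() for m in motif.regex().finditer(sequence)]


def digest(amplicon: str, motif: EnzymeMotif) -> list[int]:
    """Sorted fragment lengths after cutting at every site's offset.

    No site yields the intact amplicon; fragment lengths always sum to the
    amplicon length. Cut positions falling on the amplicon boundary or
    coinciding (overlapping sites) collapse to a single cut.
    """
    if len(amplicon) <= len(motif.recognition):
        raise ValueError("amplicon must be longer than the recognition site")
    cuts = sorted({s + motif.cut for s in find_sites(amplicon, motif)})
    cuts = [c for c in cuts if 0 < c < len(amplicon)]
    bounds = [0] + cuts + [len(amplicon)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass(frozen=True)
class AlleleAssay:
    """An allele-discrimination assay at one locus."""

    locus: str
    amplicon_b6: str
    amplicon_jf1: str
    kind: str  # "RFLP" | "sequencing_indel"
    enzyme: Optional[EnzymeMotif] = None

    def __post_init__(self) -> None:
        if self.kind not in ("RFLP", "sequencing_indel"):
            raise ValueError(f"unknown assay kind {self.kind!r}")
        if self.kind == "RFLP" and self.enzyme is None:
            raise ValueError("RFLP assay requires an enzyme")
        if self.amplicon_b6 == self.amplicon_jf1:
            raise ValueError("allele amplicons must differ")

    def amplicon(self, strain: str) -> str:
        if strain == "B6":
            return self.amplicon_b6
        if strain == "JF1":
            return self.amplicon_jf1
        raise ValueError(f"no amplicon for strain {strain!r}")


def assay_from_variant(
    variant: StrainVariant, enzyme: Optional[EnzymeMotif] = None
) -> AlleleAssay:
    """Build an assay from a strain variant (RFLP for SNVs with an enzyme,
    sequence matching for insertions)."""
    kind = "RFLP" if variant.kind == "SNV" else "sequencing_indel"
    return AlleleAssay(
        locus=variant.locus,
        amplicon_b6=variant.amplicon("B6"),
        amplicon_jf1=variant.amplicon("JF1"),
        kind=kind,
        enzyme=enzyme,
    )


def _observable(fragments: Iterable[int], floor: int) -> Counter:
    return Counter(f for f in fragments if f >= floor)


def rflp_genotype(
    observed_fragments: Sequence[int],
    assay: AlleleAssay,
    detection_floor: int = DEFAULT_DETECTION_FLOOR,
) -> str:
    """Call the expressed allele(s) from an observed fragment multiset.

    An allele is called present when its predicted (observable) digest is a
    sub-multiset of the observed fragments. Both alleles present -> "both"
    (biallelic expression); neither -> "ambiguous". An assay whose two
    predicted digests are identical cannot distinguish alleles ->
    "uninformative".
    """
    if assay.kind != "RFLP" or assay.enzyme is None:
        raise ValueError("rflp_genotype requires an RFLP assay with an enzyme")
    pred_b6 = _observable(digest(assay.amplicon_b6, assay.enzyme), detection_floor)
    pred_jf1 = _observable(digest(assay.amplicon_jf1, assay.enzyme), detection_floor)
    if pred_b6 == pred_jf1:
        return "uninformative"
    obs = _observable(observed_fragments, detection_floor)
    b6_present = not (pred_b6 - obs)
    jf1_present = not (pred_jf1 - obs)
    if b6_present and jf1_present:
        return "both"
    if b6_present:
        return "B6"
    if jf1_present:
        return "JF1"
    return "ambiguous"


def indel_genotype(observed_sequence: str, assay: AlleleAssay) -> str:
    """Call the allele of one sequenced transcript by exact window matching.

    The observed variant-spanning window must occur verbatim in exactly one
    allele's amplicon; matching both or neither is "ambiguous".
    """
    if assay.kind != "sequencing_indel":
        raise ValueError("indel_genotype requires a sequencing_indel assay")
    in_b6 = observed_sequence in assay.amplicon_b6
    in_jf1 = observed_sequence in assay.amplicon_jf1
    if in_b6 and not in_jf1:
        return "B6"
    if in_jf1 and not in_b6:
        return "JF1"
    return "ambiguous"


def aggregate_allele_calls(calls: Iterable[str]) -> str:
    """Combine per-observation allele calls for one cross.

    Both strains observed (in one call or across calls) -> "both"; no
    usable call -> "ambiguous".
    """
    seen: set[str] = set()
    for c in calls:
        if c == "both":
            return "both"
        if c in ("B6", "JF1"):
            seen.add(c)
    if seen == {"B6", "JF1"}:
        return "both"
    if len(seen) == 1:
        return next(iter(seen))
    return "ambiguous"


@dataclass(frozen=True)
class ImprintCall:
    """Parent-of-origin verdict for one locus."""

    locus: str
    verdict: str  # paternal | maternal | biallelic | inconsistent | uninformative
    observations: tuple[tuple[CrossDesign, str], ...] = ()
    provisional: bool = False


def infer_parent_of_origin(
    observations: Sequence[tuple[CrossDesign, str]], locus: str = ""
) -> ImprintCall:
    """Infer imprinting status from (cross, observed allele) pairs.

    paternal: every informative cross shows that cross's paternal X allele;
    maternal: mirror case; biallelic: both alleles seen in any cross;
    inconsistent: the observed allele tracks strain rather than parent (or
    crosses disagree); uninformative: no informative observation. A verdict
    from a single cross (no reciprocal pair) is flagged provisional.
    """
    informative = [
        (c, a)
        for c, a in observations
        if c.informative and a in ("B6", "JF1", "both")
    ]
    obs_tuple = tuple(observations)
    if not informative:
        return ImprintCall(locus, "uninformative", obs_tuple)
    provisional = len({c.paternal_x_haplotype for c, _ in informative}) < 2
    if any(a == "both" for _, a in informative):
        return ImprintCall(locus, "biallelic", obs_tuple, provisional)
    if all(a == c.paternal_x_haplotype for c, a in informative):
        return ImprintCall(locus, "paternal", obs_tuple, provisional)
    if all(a == c.maternal_x_haplotype for c, a in informative):
        return ImprintCall(locus, "maternal", obs_tuple, provisional)
    return ImprintCall(locus, "inconsistent", obs_tuple, provisional)
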
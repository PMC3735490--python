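"""Sex-differential candidate screen on per-feature read counts.

The screen mirrors a three-list candidate table:

* ``female_zero_male`` — features with 0 male reads and > ``zero_class_min_reads``
  (default 10) female reads;
* ``female_up`` — male reads > 0, female/male fold change strictly above
  ``fold_threshold`` (default 10), and at least ``min_reads`` (default 20)
  female reads;
* ``male_up`` — the symmetric male-direction list.

Filters operate on fractional read counts (not RPKM); RPKM is reported
alongside. The printed male/female ratio is computed on unrounded counts and
then rounded half-up to 3 decimals — half-up rather than banker's rounding,
because edge values such as 0.0125 must print 0.013.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence


class RatioMarker(str, Enum):
    ZERO_MALE = "ZERO_MALE"
    ZERO_FEMALE = "ZERO_FEMALE"
    BOTH_ZERO = "BOTH_ZERO"


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at the given decimal place.

    Operates on the shortest decimal representation of the double, so
    0.0125 -> 0.013 (Python's built-in round gives 0.012).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_rpkm(count: float, feature_length: int, library_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped library reads."""
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if library_mapped <= 0:
        raise ValueError("library_mapped must be positive")
    return count / ((feature_length / 1000.0) * (library_mapped / 1e6))


@dataclass(frozen=True)
class MFRatio:
    """Male/female ratio (rounded) plus a zero-denominator marker if any."""

    value: Optional[float]
    marker: Optional[RatioMarker] = None


def mf_ratio(female_reads: float, male_reads: float, ratio_decimals: int = 3) -> MFRatio:
    """Male/female read ratio, rounded half-up, with zero-count markers.

    Zero female count never divides: both-zero and zero-female cases return a
    marker with no numeric value; zero male count with nonzero female returns
    0.0 plus the ZERO_MALE marker (the zero-class eligibility signal).
    """
    if female_reads < 0 or male_reads < 0:
        raise ValueError("read counts must be non-negative")
    if female_reads == 0 and male_reads == 0:
        return MFRatio(None, RatioMarker.BOTH_ZERO)
    if female_reads == 0:
        return MFRatio(None, RatioMarker.ZERO_FEMALE)
    if male_reads == 0:
        return MFRatio(round_half_up(0.0, ratio_decimals), RatioMarker.ZERO_MALE)
    return MFRatio(round_half_up(male_reads / female_reads, ratio_decimals), None)


@dataclass(frozen=True)
class CountRecord:
    """Per-feature fractional counts and normalized abundances per sex."""

    feature_id: str
    rna_type: str
    female_reads: float
    male_reads: float
    chromosome: str
    female_rpkm: float = 0.0
    male_rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.female_reads < 0 or self.male_reads < 0:
            raise ValueError("counts must be non-negative")
        if self.female_rpkm < 0 or self.male_rpkm < 0:
            raise ValueError("RPKM must be non-negative")


@dataclass(frozen=True)
class ScreenParams:
    fold_threshold: float = 10.0
    min_reads: float = 20.0
    zero_class_min_reads: float = 10.0
    ratio_decimals: int = 3
    reads_decimals: int = 2

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "min_reads", "zero_class_min_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ratio_decimals <= 0 or self.reads_decimals <= 0:
            raise ValueError("decimal settings must be > 0")


@dataclass(frozen=True)
class ScreenHit:
    record: CountRecord
    ratio: MFRatio


@dataclass
class ScreenResult:
    female_zero_male: list[ScreenHit] = field(default_factory=list)
    female_up: list[ScreenHit] = field(default_factory=list)
    male_up: list[ScreenHit] = field(default_factory=list)


def screen(records: Sequence[CountRecord], params: ScreenParams = ScreenParams()) -> ScreenResult:
    """Apply the filter cascade to a count table.

    Filter semantics (strict where the rules say "more than", inclusive for
    the read floor):

    * zero class:  male == 0 and female > zero_class_min_reads
    * female up:   male > 0 and female/male > fold_threshold and female >= min_reads
    * male up:     female > 0 and male/female > fold_threshold and male >= min_reads

    Female-direction lists are sorted by ascending M/F ratio (ties broken by
    descending female reads); the male list by descending ratio.
    """
    result = ScreenResult()
    for rec in records:
        r = mf_ratio(rec.female_reads, rec.male_reads, params.ratio_decimals)
        if rec.male_reads == 0 and rec.female_reads > params.zero_class_min_reads:
            result.female_zero_male.append(ScreenHit(rec, r))
        elif (
            rec.male_reads > 0
            and rec.female_reads / rec.male_reads > params.fold_threshold
            and rec.female_reads >= params.min_reads
        ):
            result.female_up.append(ScreenHit(rec, r))
        elif (
            rec.female_reads > 0
            and rec.male_reads / rec.female_reads > params.fold_threshold
            and rec.male_reads >= params.min_reads
        ):
            result.male_up.append(ScreenHit(rec, r))
    result.female_zero_male.sort(key=lambda h: (-h.record.female_reads, h.record.feature_id))
    result.female_up.sort(
        key=lambda h: (h.ratio.value, -h.record.female_reads, h.record.feature_id)
    )
    result.male_up.sort(
        key=lambda h: (-(h.ratio.value or 0.0), -h.record.male_reads, h.record.feature_id)
    )
    return result
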
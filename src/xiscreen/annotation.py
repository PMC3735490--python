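"""Read classification into the ncRNA taxonomy, with the "only genomic"
fallback and the secondary repeat/tRNA pass.

A mapped read is assigned a feature when one of its hits overlaps the
feature interval by at least ``min_overlap_frac`` of the read length and, for
ncRNA classes, lies on the same strand (mature miRNAs are stranded). A read
may carry several class labels at once — one read wholly inside a mature
miRNA also overlaps the surrounding hairpin, and it is counted once in each
class row. Consequently the genome-mapped total need not equal
total-ncRNA + only-genomic.

Reads with no ncRNA label are "only genomic"; those are re-annotated against
repeat and tRNA intervals (strand-agnostic, repeat wins ties) to estimate the
degradation-product fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .mapping import MappingResult, WeightedHit
from .model import RNA_CLASSES, SECONDARY_CLASSES, AnnotationFeature

DEFAULT_MIN_OVERLAP_FRAC = 0.5


def _min_overlap(frac: float, read_len: int) -> int:
    """Required overlap in nt: ceil(frac * read_len), at least 1."""
    return max(1, math.ceil(frac * read_len))


def _build_trees(features: Iterable[AnnotationFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _overlapping_features(
    trees: dict[str, IntervalTree],
    chrom: str,
    start: int,
    end: int,
    strand: Optional[str],
    min_overlap: int,
) -> list[AnnotationFeature]:
    tree = trees.get(chrom)
    if tree is None:
        return []
    out = []
    for iv in tree.overlap(start, end):
        feat: AnnotationFeature = iv.data
        if strand is not None and feat.strand != strand:
            continue
        if min(end, feat.end) - max(start, feat.start) >= min_overlap:
            out.append(feat)
    return out


def assign_classes(
    result: MappingResult,
    features: Iterable[AnnotationFeature],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    stranded: bool = True,
) -> dict[str, set[str]]:
    """Per-read set of ncRNA class labels (empty set = "only genomic").

    Repeat-like reads (over the multi-hit cap) are never assigned an ncRNA
    class; they fall through to the only-genomic pool.
    """
    ncrna = [f for f in features if f.class_label in RNA_CLASSES]
    trees = _build_trees(ncrna)
    assignments: dict[str, set[str]] = {}
    for rid, hits in result.hits.items():
        labels: set[str] = set()
        if rid not in result.repeat_like:
            for h in hits:
                need = _min_overlap(min_overlap_frac, h.end - h.start)
                for feat in _overlapping_features(
                    trees, h.chrom, h.start, h.end,
                    h.strand if stranded else None, need,
                ):
                    labels.add(feat.class_label)
        assignments[rid] = labels
    return assignments


def assign_features(
    weighted_hits: Iterable[WeightedHit],
    features: Iterable[AnnotationFeature],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    stranded: bool = True,
    exclude_reads: Optional[set[str]] = None,
) -> dict[str, Fraction]:
    """Per-feature fractional read counts.

    Each weighted hit contributes its full weight to every feature it
    overlaps (a read inside a mature miRNA counts toward the mature, the
    hairpin and any host gene alike); weights are only split across genomic
    *loci*, not across overlapping annotations of one locus.
    """
    trees = _build_trees(list(features))
    counts: dict[str, Fraction] = {}
    skip = exclude_reads or set()
    for wh in weighted_hits:
        if wh.read_id in skip:
            continue
        need = _min_overlap(min_overlap_frac, wh.end - wh.start)
        for feat in _overlapping_features(
            trees, wh.chrom, wh.start, wh.end, wh.strand if stranded else None, need
        ):
            counts[feat.feature_id] = counts.get(feat.feature_id, Fraction(0)) + wh.weight
    return counts


@dataclass
class ClassificationSummary:
    """Per-library classification in summary-table row order."""

    sex: str
    n_reads: int
    genome_mapped: int
    class_counts: dict[str, int]
    total_ncrna: int
    only_genomic: int
    secondary_fractions: dict[str, float] = field(default_factory=dict)

    def rows(self) -> list[tuple[str, int]]:
        out = [("No. reads", self.n_reads), ("Genome mapped", self.genome_mapped)]
        out += [(c, self.class_counts.get(c, 0)) for c in RNA_CLASSES]
        out += [("(Total ncRNA)", self.total_ncrna), ("Only genomic", self.only_genomic)]
        return out


def summarize(
    result: MappingResult,
    assignments: dict[str, set[str]],
    sex: str,
) -> ClassificationSummary:
    """Count reads per class (multiplicity-weighted).

    ``total_ncrna`` counts reads with at least one ncRNA label; because a
    read can sit in several class rows at once, it need not equal the sum of
    the class rows, and genome_mapped need not equal total_ncrna +
    only_genomic.
    """
    class_counts = {c: 0 for c in RNA_CLASSES}
    total_ncrna = 0
    only_genomic = 0
    for rid, labels in assignments.items():
        mult = result.reads[rid].multiplicity
        if labels:
            total_ncrna += mult
            for c in labels:
                class_counts[c] += mult
        else:
            only_genomic += mult
    return ClassificationSummary(
        sex=sex,
        n_reads=result.total_read_count,
        genome_mapped=result.mapped_read_count,
        class_counts=class_counts,
        total_ncrna=total_ncrna,
        only_genomic=only_genomic,
    )


def secondary_annotation(
    result: MappingResult,
    assignments: dict[str, set[str]],
    features: Iterable[AnnotationFeature],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> dict[str, str]:
    """Label each only-genomic read repeat / tRNA / unannotated.

    The pass is strand-agnostic (degradation fragments have no defined
    polarity) and repeat takes precedence when a read overlaps both a repeat
    and a tRNA.
    """
    secondary = [f for f in features if f.class_label in SECONDARY_CLASSES]
    trees = _build_trees(secondary)
    labels: dict[str, str] = {}
    for rid, classes in assignments.items():
        if classes:
            continue  # not only-genomic
        hit_classes: set[str] = set()
        for h in result.hits[rid]:
            need = _min_overlap(min_overlap_frac, h.end - h.start)
            for feat in _overlapping_features(trees, h.chrom, h.start, h.end, None, need):
                hit_classes.add(feat.class_label)
        if "repeat" in hit_classes:
            labels[rid] = "repeat"
        elif "tRNA" in hit_classes:
            labels[rid] = "tRNA"
        else:
            labels[rid] = "unannotated"
    return labels


def secondary_fractions(
    result: MappingResult, secondary_labels: dict[str, str]
) -> dict[str, float]:
    """Multiplicity-weighted fractions of only-genomic reads per secondary label."""
    totals = {"repeat": 0, "tRNA": 0, "unannotated": 0}
    for rid, label in secondary_labels.items():
        totals[label] += result.reads[rid].multiplicity
    denom = sum(totals.values())
    if denom == 0:
        return {k: 0.0 for k in totals}
    return {k: v / denom for k, v in totals.items()}
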
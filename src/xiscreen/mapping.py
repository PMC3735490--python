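"""Exact-match short-read mapping with fractional multi-map counting.

Only perfect, full-length matches count: a read either occurs verbatim in
the genome (forward, or as reverse complement on the minus strand) or it is
unmapped and excluded from all downstream counts. A read with k equally good
hits contributes weight 1/k to each — weights are carried as exact
``fractions.Fraction`` so that the total contributed weight per library
equals the mapped read count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .model import DNA_ALPHABET, GenomeRef, PerfectHit, SmallRNARead, revcomp

MIN_READ_LEN = 18
MAX_READ_LEN = 26

_SEED_LEN = MIN_READ_LEN


class GenomeIndex:
    """Exact-occurrence index over both strands of a genome.

    Seeds on the forward-strand 18-mers (the minimum read length); a query
    of length 18–26 is located by seed lookup and full-length verification,
    on both strands. Minus-strand hits are reported in forward-genome
    coordinates with strand "-".
    """

    def __init__(self, genome: GenomeRef):
        if not genome.chromosomes or all(len(s) == 0 for s in genome.chromosomes.values()):
            raise ValueError("cannot index an empty genome")
        self.genome = genome
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.chromosomes.items():
            for pos in range(len(seq) - _SEED_LEN + 1):
                self._seeds.setdefault(seq[pos : pos + _SEED_LEN], []).append((chrom, pos))

    def _forward_occurrences(self, query: str) -> list[tuple[str, int]]:
        hits = []
        n = len(query)
        for chrom, pos in self._seeds.get(query[:_SEED_LEN], ()):  # verify extension
            if self.genome.chromosomes[chrom][pos : pos + n] == query:
                hits.append((chrom, pos))
        return hits

    def find(self, query: str, read_id: str = "query") -> list[PerfectHit]:
        """All exact occurrences of ``query`` on either strand."""
        if not (MIN_READ_LEN <= len(query) <= MAX_READ_LEN):
            raise ValueError(
                f"query length {len(query)} outside [{MIN_READ_LEN}, {MAX_READ_LEN}]"
            )
        n = len(query)
        hits = [
            PerfectHit(read_id, chrom, pos, pos + n, "+")
            for chrom, pos in self._forward_occurrences(query)
        ]
        hits += [
            PerfectHit(read_id, chrom, pos, pos + n, "-")
            for chrom, pos in self._forward_occurrences(revcomp(query))
        ]
        return hits


def build_index(genome: GenomeRef) -> GenomeIndex:
    return GenomeIndex(genome)


@dataclass
class MappingResult:
    """Outcome of mapping one or more libraries."""

    hits: dict[str, list[PerfectHit]]            # read_id -> perfect hits
    reads: dict[str, SmallRNARead]               # mapped reads by id
    unmapped: dict[str, str]                     # read_id -> reason
    repeat_like: set[str] = field(default_factory=set)  # ids over the hit cap

    def __post_init__(self) -> None:
        self._unmapped_reads: dict[str, SmallRNARead] = {}

    @property
    def mapped_read_count(self) -> int:
        """Number of mapped sequenced reads (multiplicity-weighted)."""
        return sum(self.reads[rid].multiplicity for rid in self.hits)

    @property
    def total_read_count(self) -> int:
        """All sequenced reads, mapped or not (multiplicity-weighted)."""
        unmapped = sum(r.multiplicity for r in self._unmapped_reads.values())
        return self.mapped_read_count + unmapped

    def record_unmapped(self, read: SmallRNARead, reason: str) -> None:
        self.unmapped[read.read_id] = reason
        self._unmapped_reads[read.read_id] = read


def collapse_reads(reads: Iterable[SmallRNARead]) -> list[SmallRNARead]:
    """Merge identical sequences within a library into multiplicity counts.

    The collapsed read keeps the first id seen for that sequence.
    """
    merged: dict[tuple[str, str], list] = {}
    for r in reads:
        key = (r.library_sex, r.sequence)
        if key in merged:
            merged[key][1] += r.multiplicity
        else:
            merged[key] = [r, r.multiplicity]
    return [
        SmallRNARead(first.read_id, first.sequence, first.library_sex, mult)
        for first, mult in merged.values()
    ]


def map_reads(
    reads: Iterable[SmallRNARead],
    index: GenomeIndex,
    max_hits: int = 200,
) -> MappingResult:
    """Map reads against the index; perfect full-length matches only.

    Reads with non-ACGT symbols or out-of-range length are rejected with a
    reason. Reads matching more than ``max_hits`` loci are flagged
    repeat-like: they stay mapped (they count in the genome-mapped total and
    the only-genomic/repeat summary) but are excluded from per-feature
    counting.
    """
    result = MappingResult(hits={}, reads={}, unmapped={})
    cache: dict[str, list[PerfectHit]] = {}
    for read in reads:
        if not set(read.sequence) <= DNA_ALPHABET:
            result.record_unmapped(read, "non-ACGT symbol in sequence")
            continue
        if not (MIN_READ_LEN <= len(read) <= MAX_READ_LEN):
            result.record_unmapped(read, f"length {len(read)} outside 18-26")
            continue
        if read.sequence in cache:
            template = cache[read.sequence]
        else:
            template = index.find(read.sequence, read_id="")
            cache[read.sequence] = template
        if not template:
            result.record_unmapped(read, "no perfect match")
            continue
        result.hits[read.read_id] = [
            PerfectHit(read.read_id, h.chrom, h.start, h.end, h.strand) for h in template
        ]
        result.reads[read.read_id] = read
        if len(template) > max_hits:
            result.repeat_like.add(read.read_id)
    return result


@dataclass(frozen=True)
class WeightedHit:
    """A perfect hit carrying its fractional count contribution."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    weight: Fraction


def fractional_counts(result: MappingResult) -> list[WeightedHit]:
    """Split each read's multiplicity equally over its k hits (weight m/k).

    Total weight over all hits of a read equals its multiplicity exactly
    (Fraction arithmetic), so library-wide weights sum to the mapped read
    count.
    """
    weighted: list[WeightedHit] = []
    for rid, hits in result.hits.items():
        k = len(hits)
        if k == 0:
            raise ValueError(f"read {rid!r} has no hits")
        w = Fraction(result.reads[rid].multiplicity, k)
        weighted.extend(
            WeightedHit(rid, h.chrom, h.start, h.end, h.strand, w) for h in hits
        )
    return weighted
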
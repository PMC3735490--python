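"""Classification taxonomy: overlap rules, multiple annotations, secondary pass."""

import numpy as np

from xiscreen.annotation import (
    assign_classes,
    assign_features,
    secondary_annotation,
    secondary_fractions,
    summarize,
)
from xiscreen.mapping import build_index, fractional_counts, map_reads
from xiscreen.model import AnnotationFeature, GenomeRef, SmallRNARead, revcomp


def make_genome(seed=0, length=3_000):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    x = "".join(rng.choice(list("ACGT"), size=length // 2))
    return GenomeRef({"chr1": seq, "chrX": x}, x_chrom="chrX")


def reads_from(genome, spans, sex="female"):
    """One read per (chrom, start, length, strand, id)."""
    out = []
    for chrom, start, length, strand, rid in spans:
        seq = genome.chromosomes[chrom][start : start + length]
        out.append(SmallRNARead(rid, revcomp(seq) if strand == "-" else seq, sex))
    return out


def test_read_inside_feature_same_strand_gets_single_label():
    genome = make_genome()
    feat = AnnotationFeature("m1", "miRNA_mature", "chr1", 100, 122)
    reads = reads_from(genome, [("chr1", 100, 22, "+", "r1")])
    result = map_reads(reads, build_index(genome))
    assert assign_classes(result, [feat])["r1"] == {"miRNA_mature"}


def test_strand_discordant_read_is_not_assigned():
    genome = make_genome()
    feat = AnnotationFeature("m1", "miRNA_mature", "chr1", 100, 122, "-")
    reads = reads_from(genome, [("chr1", 100, 22, "+", "r1")])
    result = map_reads(reads, build_index(genome))
    assert assign_classes(result, [feat])["r1"] == set()


def test_half_overlap_rule_boundary():
    genome = make_genome()
    feat = AnnotationFeature("m1", "miRNA_mature", "chr1", 100, 200)
    # 22 nt read needs >= 11 nt inside the feature
    result = map_reads(
        reads_from(genome, [("chr1", 89, 22, "+", "just_in"), ("chr1", 88, 22, "+", "just_out")]),
        build_index(genome),
    )
    classes = assign_classes(result, [feat])
    assert classes["just_in"] == {"miRNA_mature"}
    assert classes["just_out"] == set()


def test_nested_mature_and_hairpin_both_counted():
    """A read inside a mature miRNA also lies in the surrounding hairpin:
    it carries both labels and is counted once per class row, so the mapped
    total need not equal total-ncRNA + only-genomic."""
    genome = make_genome()
    hairpin = AnnotationFeature("hp", "miRNA_hairpin", "chr1", 90, 170)
    mature = AnnotationFeature("m", "miRNA_mature", "chr1", 100, 122)
    reads = reads_from(genome, [("chr1", 100, 22, "+", "r1")])
    result = map_reads(reads, build_index(genome))
    assignments = assign_classes(result, [hairpin, mature])
    assert assignments["r1"] == {"miRNA_mature", "miRNA_hairpin"}
    summary = summarize(result, assignments, "female")
    assert summary.class_counts["miRNA_mature"] == 1
    assert summary.class_counts["miRNA_hairpin"] == 1
    assert summary.total_ncrna == 1
    assert summary.genome_mapped == 1
    assert summary.total_ncrna + summary.only_genomic != sum(summary.class_counts.values())


def test_assignments_match_quadratic_overlap_oracle():
    """Class sets equal an all-pairs interval/strand check."""
    genome = make_genome(seed=1)
    rng = np.random.default_rng(42)
    classes = ["miRNA_mature", "snoRNA", "lincRNA", "rRNA"]
    features = []
    for i in range(30):
        chrom = "chr1" if rng.random() < 0.7 else "chrX"
        start = int(rng.integers(0, len(genome.chromosomes[chrom]) - 150))
        length = int(rng.integers(20, 150))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            AnnotationFeature(f"f{i}", classes[i % 4], chrom, start, start + length, strand)
        )
    spans = []
    for i in range(80):
        chrom = "chr1" if rng.random() < 0.7 else "chrX"
        n = int(rng.integers(18, 27))
        start = int(rng.integers(0, len(genome.chromosomes[chrom]) - n))
        strand = "+" if rng.random() < 0.5 else "-"
        spans.append((chrom, start, n, strand, f"r{i}"))
    result = map_reads(reads_from(genome, spans), build_index(genome))
    got = assign_classes(result, features)
    # oracle: quadratic loop over every (hit, feature) pair
    for rid, hits in result.hits.items():
        expected = set()
        for h in hits:
            for f in features:
                if f.chrom != h.chrom or f.strand != h.strand:
                    continue
                overlap = min(h.end, f.end) - max(h.start, f.start)
                if overlap >= int(np.ceil(0.5 * (h.end - h.start))):
                    expected.add(f.class_label)
        assert got[rid] == expected, rid


def test_summary_of_unannotated_library():
    genome = make_genome()
    reads = reads_from(genome, [("chr1", i * 40, 20, "+", f"r{i}") for i in range(10)])
    result = map_reads(reads, build_index(genome))
    assignments = assign_classes(result, [])
    summary = summarize(result, assignments, "female")
    assert summary.only_genomic == 10
    assert summary.total_ncrna == 0
    assert all(v == 0 for v in summary.class_counts.values())
    assert summary.n_reads == 10  # conservation of multiplicities


def test_class_counts_monotone_when_features_added():
    genome = make_genome(seed=2)
    spans = [("chr1", i * 37, 22, "+", f"r{i}") for i in range(40)]
    result = map_reads(reads_from(genome, spans), build_index(genome))
    base = [AnnotationFeature("a", "snoRNA", "chr1", 0, 400)]
    extra = base + [AnnotationFeature("b", "snoRNA", "chr1", 400, 900),
                    AnnotationFeature("c", "rRNA", "chr1", 900, 1400)]
    s1 = summarize(result, assign_classes(result, base), "female")
    s2 = summarize(result, assign_classes(result, extra), "female")
    for cls in s1.class_counts:
        assert s2.class_counts[cls] >= s1.class_counts[cls]


def test_secondary_pass_recovers_planted_mixture_exactly():
    """Only-genomic reads planted 50/20/30 across repeat/tRNA/background."""
    genome = make_genome(seed=3)
    repeat = AnnotationFeature("rep", "repeat", "chr1", 100, 300)
    trna = AnnotationFeature("trn", "tRNA", "chr1", 500, 572)
    spans = (
        [("chr1", 120 + i, 22, "+", f"rep{i}") for i in range(5)]
        + [("chr1", 510 + i, 22, "+", f"trn{i}") for i in range(2)]
        + [("chr1", 1000 + 40 * i, 22, "+", f"bg{i}") for i in range(3)]
    )
    result = map_reads(reads_from(genome, spans), build_index(genome))
    assignments = assign_classes(result, [repeat, trna])  # no ncRNA features
    assert all(v == set() for v in assignments.values())
    labels = secondary_annotation(result, assignments, [repeat, trna])
    fracs = secondary_fractions(result, labels)
    assert fracs == {"repeat": 0.5, "tRNA": 0.2, "unannotated": 0.3}


def test_secondary_pass_is_strand_agnostic_and_repeat_wins_ties():
    genome = make_genome(seed=4)
    repeat = AnnotationFeature("rep", "repeat", "chr1", 100, 200, "+")
    trna = AnnotationFeature("trn", "tRNA", "chr1", 150, 222, "+")
    spans = [("chr1", 120, 22, "-", "minus_read"), ("chr1", 160, 22, "+", "both_read")]
    result = map_reads(reads_from(genome, spans), build_index(genome))
    assignments = assign_classes(result, [repeat, trna])
    labels = secondary_annotation(result, assignments, [repeat, trna])
    assert labels["minus_read"] == "repeat"  # opposite strand still matches
    assert labels["both_read"] == "repeat"  # repeat precedence over tRNA


def test_no_secondary_features_leaves_all_unannotated():
    genome = make_genome(seed=5)
    result = map_reads(reads_from(genome, [("chr1", 50, 22, "+", "r0")]), build_index(genome))
    assignments = assign_classes(result, [])
    labels = secondary_annotation(result, assignments, [])
    assert labels == {"r0": "unannotated"}


def test_feature_counts_accumulate_weights_per_feature():
    genome = make_genome(seed=6)
    feat = AnnotationFeature("m1", "miRNA_mature", "chr1", 100, 130)
    reads = reads_from(genome, [("chr1", 100, 22, "+", "r1"), ("chr1", 105, 22, "+", "r2")])
    result = map_reads(reads, build_index(genome))
    counts = assign_features(fractional_counts(result), [feat])
    assert counts["m1"] == 2
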
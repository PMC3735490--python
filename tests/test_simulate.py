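"""Synthetic-data generator: determinism, structure, and noise calibration."""

import numpy as np
import pytest

from xiscreen.model import GenomeRef, AnnotationFeature, RNA_CLASSES, revcomp, reciprocal_crosses
from xiscreen.simulate import (
    ExpressionModel,
    FeatureExpression,
    default_expression_model,
    make_toy_genome,
    simulate_f1_transcripts,
    simulate_libraries,
    simulate_qpcr,
)


def test_toy_genome_is_deterministic():
    g1, f1, v1 = make_toy_genome(1, 20_000, 20_000)
    g2, f2, v2 = make_toy_genome(1, 20_000, 20_000)
    assert g1.chromosomes == g2.chromosomes
    assert f1 == f2 and v1 == v2
    g3, _, _ = make_toy_genome(2, 20_000, 20_000)
    assert g3.chromosomes != g1.chromosomes


def test_toy_genome_rejects_short_chromosomes():
    with pytest.raises(ValueError):
        make_toy_genome(1, 5_000, 20_000)


def test_toy_genome_structure(toy):
    genome, features, variants = toy
    # every ncRNA class represented, plus repeat and tRNA intervals
    classes = {f.class_label for f in features}
    assert set(RNA_CLASSES) <= classes
    assert {"repeat", "tRNA"} <= classes
    # all intervals within chromosome bounds
    for f in features:
        assert 0 <= f.start < f.end <= len(genome.chromosomes[f.chrom])
    # at least 3 variants, with an enzyme-site SNV and an insertion
    assert len(variants) >= 3
    kinds = {v.kind for v in variants}
    assert kinds == {"SNV", "insertion"}


def test_spiked_mirnas_cluster_inside_one_host_gene(toy):
    """The two X-linked mature miRNAs sit adjacent within a single host-gene
    interval, like a clustered miRNA pair in a host lncRNA intron."""
    genome, features, _ = toy
    matures = [
        f for f in features
        if f.class_label == "miRNA_mature" and f.chrom == genome.x_chrom
    ]
    assert len(matures) >= 2
    hosts = [
        h for h in features
        if h.class_label == "lincRNA" and h.chrom == genome.x_chrom
    ]
    containing = [
        h for h in hosts
        if all(h.start <= m.start and m.end <= h.end for m in matures)
    ]
    assert containing, "X-linked matures must share one host interval"
    matures.sort(key=lambda m: m.start)
    assert matures[1].start - matures[0].end < 200  # adjacent


def test_repeat_copies_share_sequence(toy):
    genome, features, _ = toy
    units = {
        genome.chromosomes[f.chrom][f.start : f.end]
        for f in features
        if f.class_label == "repeat"
    }
    assert len(units) == 1  # one family, identical copies


def test_library_reads_are_genomic_substrings(toy, toy_model):
    genome, features, _ = toy
    female, male = simulate_libraries(genome, features, toy_model, 500, seed=7)
    assert female and male
    chroms = list(genome.chromosomes.values())
    for read in female + male:
        assert 18 <= len(read) <= 26
        assert any(read.sequence in c or revcomp(read.sequence) in c for c in chroms)
    assert all(r.library_sex == "female" for r in female)
    assert all(r.library_sex == "male" for r in male)


def test_libraries_deterministic_and_seed_sensitive(toy, toy_model):
    genome, features, _ = toy
    a = simulate_libraries(genome, features, toy_model, 300, seed=3)
    b = simulate_libraries(genome, features, toy_model, 300, seed=3)
    c = simulate_libraries(genome, features, toy_model, 300, seed=4)
    assert a == b
    assert a != c


@pytest.mark.parametrize("seed", range(1, 11))
def test_paternal_x_features_yield_zero_male_reads(toy, toy_model, seed):
    """Males carry no paternal X: every seeded run has exactly zero male
    reads from paternally imprinted X-linked features."""
    genome, features, _ = toy
    paternal = {
        fid for fid, e in toy_model.features.items()
        if e.imprint_mode == "paternal" and e.x_linked
    }
    assert paternal
    female, male = simulate_libraries(genome, features, toy_model, 300, seed=seed)
    male_sources = {r.read_id.split("_", 1)[1].rsplit("_", 1)[0] for r in male}
    assert not (paternal & male_sources)
    female_sources = {r.read_id.split("_", 1)[1].rsplit("_", 1)[0] for r in female}
    assert {"mir374", "mir421"} <= female_sources


def test_unmappable_fraction_plants_absent_reads(toy, toy_model):
    genome, features, _ = toy
    female, _ = simulate_libraries(
        genome, features, toy_model, 500, seed=5, unmappable_fraction=0.1
    )
    planted = [r for r in female if "unmappable" in r.read_id]
    assert planted
    chroms = list(genome.chromosomes.values())
    for r in planted:
        assert not any(r.sequence in c or revcomp(r.sequence) in c for c in chroms)


def test_null_model_gives_empty_libraries():
    genome = GenomeRef({"chrX": "ACGT" * 200}, x_chrom="chrX")
    feat = AnnotationFeature("f1", "lincRNA", "chrX", 100, 200)
    model = ExpressionModel({"f1": FeatureExpression(0, 0)}, degradation_fraction=0.0)
    female, male = simulate_libraries(genome, [feat], model, 100, seed=1)
    assert female == [] and male == []


def test_model_referencing_unknown_feature_errors(toy):
    genome, features, _ = toy
    model = ExpressionModel({"nope": FeatureExpression(5, 5)}, degradation_fraction=0.0)
    with pytest.raises(ValueError, match="unknown feature"):
        simulate_libraries(genome, features, model, 100, seed=1)


def test_paternal_x_model_with_male_mean_rejected():
    with pytest.raises(ValueError):
        FeatureExpression(10, 5, imprint_mode="paternal", x_linked=True)


def test_feature_counts_match_poisson_mean():
    """Monte-Carlo: empirical per-feature mean over many seeded libraries
    agrees with the Poisson oracle (within 3 standard errors)."""
    rng_seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=600))
    genome = GenomeRef({"chrX": rng_seq}, x_chrom="chrX")
    feat = AnnotationFeature("f1", "lincRNA", "chrX", 100, 200)
    model = ExpressionModel({"f1": FeatureExpression(40, 40)}, degradation_fraction=0.0)
    n_rep = 4000
    counts = [
        len(simulate_libraries(genome, [feat], model, 1, seed=s)[0])
        for s in range(n_rep)
    ]
    mean = np.mean(counts)
    se = np.sqrt(40 / n_rep)
    assert abs(mean - 40) < 3 * se


def test_f1_transcripts_follow_parent_of_origin(toy):
    _, _, variants = toy
    snv = next(v for v in variants if v.kind == "SNV")
    cross_jb, cross_bf = reciprocal_crosses()
    # paternal expression: the observed allele is the paternal X haplotype
    for cross, allele in ((cross_jb, "B6"), (cross_bf, "JF1")):
        transcripts = simulate_f1_transcripts(cross, snv, "paternal", 50, seed=2)
        assert set(transcripts) == {snv.amplicon(allele)}
    # maternal mirror
    transcripts = simulate_f1_transcripts(cross_jb, snv, "maternal", 50, seed=2)
    assert set(transcripts) == {snv.amplicon("JF1")}


def test_f1_biallelic_mode_is_symmetric(toy):
    _, _, variants = toy
    snv = variants[0]
    n = 10_000
    transcripts = simulate_f1_transcripts(
        reciprocal_crosses()[0], snv, "none", n, seed=11
    )
    b6 = sum(t == snv.amplicon("B6") for t in transcripts)
    assert abs(b6 / n - 0.5) < 3 * np.sqrt(0.25 / n)


def test_f1_unknown_strain_errors(toy):
    _, _, variants = toy
    with pytest.raises(ValueError, match="strain"):
        variants[0].amplicon("CAST")


def test_qpcr_noiseless_limit():
    df = simulate_qpcr(2.5, 0.3, cv=0.0, n_reps=3, seed=1)
    assert set(df[df.sex == "female"].value) == {2.5}
    assert set(df[df.sex == "male"].value) == {0.3}
    assert sorted(df.replicate.unique()) == [1, 2, 3]


def test_qpcr_cv_recovered():
    """Sample CV over many replicates matches the lognormal target within 5%."""
    df = simulate_qpcr(1.0, 1.0, cv=0.1, n_reps=10_000, seed=3)
    vals = df[df.sex == "female"].value
    cv_hat = vals.std(ddof=1) / vals.mean()
    assert abs(cv_hat - 0.1) < 0.005


def test_qpcr_rejects_bad_inputs():
    with pytest.raises(ValueError):
        simulate_qpcr(1.0, 1.0, cv=-0.1, n_reps=3, seed=1)
    with pytest.raises(ValueError):
        simulate_qpcr(1.0, 1.0, cv=0.1, n_reps=1, seed=1)
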
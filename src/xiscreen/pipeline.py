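"""End-to-end orchestration: simulate -> map -> annotate -> screen ->
verify imprinting -> qPCR statistics.

Every stage output lands in the configured directory with a comment header
recording the seed and parameters; a JSON manifest lists all outputs. Given
the same config the run is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import yaml

from . import __version__, io as xio
from .annotation import (
    assign_classes,
    assign_features,
    secondary_annotation,
    secondary_fractions,
    summarize,
)
from .mapping import build_index, fractional_counts, map_reads
from .model import AnnotationFeature, StrainVariant, reciprocal_crosses
from .rflp import (
    BUILTIN_ENZYMES,
    aggregate_allele_calls,
    assay_from_variant,
    digest,
    indel_genotype,
    infer_parent_of_origin,
    rflp_genotype,
)
from .screen import CountRecord, ScreenParams, compute_rpkm, screen
from .simulate import (
    default_expression_model,
    make_toy_genome,
    simulate_f1_transcripts,
    simulate_libraries,
    simulate_qpcr,
)
from .stats import sex_bias_test

log = logging.getLogger("xiscreen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "xiscreen_out"
    autosome_length: int = 50_000
    x_length: int = 50_000
    n_reads_per_sex: int = 5_000
    unmappable_fraction: float = 0.08
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    alpha: float = 0.01
    qpcr_cv: float = 0.1
    qpcr_n_reps: int = 3
    f1_transcripts_per_cross: int = 200
    imprint_mode: str = "paternal"  # planted truth for the variant loci
    min_overlap_frac: float = 0.5
    max_hits: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sp = raw.pop("screen_params", None)
        cfg = cls(**raw)
        if sp:
            cfg.screen_params = ScreenParams(**sp)
        return cfg


def _subseed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def informative_enzyme(variant: StrainVariant):
    """First built-in enzyme whose predicted digests differ between alleles."""
    for enzyme in BUILTIN_ENZYMES.values():
        a, b = variant.amplicon("B6"), variant.amplicon("JF1")
        if min(len(a), len(b)) <= len(enzyme.recognition):
            continue
        if digest(a, enzyme) != digest(b, enzyme):
            return enzyme
    return None


def build_count_records(
    features: list[AnnotationFeature],
    female_result,
    male_result,
    min_overlap_frac: float = 0.5,
) -> list[CountRecord]:
    """Per-feature count table over ncRNA-class features, with RPKM."""
    from .model import RNA_CLASSES

    ncrna = [f for f in features if f.class_label in RNA_CLASSES]
    per_sex = {}
    mapped = {}
    for sex, result in (("female", female_result), ("male", male_result)):
        weighted = fractional_counts(result)
        per_sex[sex] = assign_features(
            weighted, ncrna, min_overlap_frac=min_overlap_frac,
            exclude_reads=result.repeat_like,
        )
        mapped[sex] = result.mapped_read_count
    records = []
    for f in ncrna:
        fc = float(per_sex["female"].get(f.feature_id, 0))
        mc = float(per_sex["male"].get(f.feature_id, 0))
        records.append(
            CountRecord(
                feature_id=f.feature_id,
                rna_type=f.class_label,
                female_reads=fc,
                male_reads=mc,
                chromosome=f.chrom,
                female_rpkm=compute_rpkm(fc, f.length, mapped["female"]) if mapped["female"] else 0.0,
                male_rpkm=compute_rpkm(mc, f.length, mapped["male"]) if mapped["male"] else 0.0,
            )
        )
    return records


def verify_imprinting(
    variants: list[StrainVariant],
    imprint_mode: str,
    n_per_cross: int,
    seed: int,
):
    """Simulate F1 transcripts for each variant under reciprocal crosses,
    genotype them (RFLP for SNVs, sequence matching for indels) and infer
    parent of origin."""
    calls = []
    crosses = reciprocal_crosses()
    for vi, variant in enumerate(variants):
        enzyme = informative_enzyme(variant) if variant.kind == "SNV" else None
        assay = assay_from_variant(variant, enzyme)
        observations = []
        for ci, cross in enumerate(crosses):
            transcripts = simulate_f1_transcripts(
                cross, variant, imprint_mode, n_per_cross, _subseed(seed, 10 + 7 * vi + ci)
            )
            if assay.kind == "RFLP":
                observed: list[int] = []
                for t in transcripts:
                    observed.extend(digest(t, assay.enzyme))
                allele = rflp_genotype(observed, assay)
            else:
                allele = aggregate_allele_calls(
                    indel_genotype(t, assay) for t in transcripts
                )
            observations.append((cross, allele))
        calls.append(infer_parent_of_origin(observations, locus=variant.locus))
    return calls


#: qPCR panel simulated alongside the screen: (gene, true female ratio,
#: true male ratio). The two planted miRNAs are strongly female-biased; the
#: autosomal control is balanced.
QPCR_PANEL = (
    ("mir374", 1.0, 0.05),
    ("mir421", 0.8, 0.04),
    ("mir_ctrl", 1.0, 1.0),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns key results in memory.

    Writes genome/annotations/reads plus all stage tables and a manifest to
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "xiscreen",
        "version": __version__,
        "config": asdict(config),
        "outputs": {},
    }
    # out_dir is excluded from file headers so that runs into different
    # directories with the same seed stay byte-identical.
    header_params = {k: v for k, v in manifest["config"].items() if k != "out_dir"}
    header = {"seed": config.seed, "params": json.dumps(header_params, sort_keys=True)}

    def _out(name: str, fname: str) -> Path:
        p = out / fname
        manifest["outputs"][name] = fname
        return p

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = _stage("simulate")
        genome, features, variants = make_toy_genome(
            config.seed, config.autosome_length, config.x_length
        )
        model = default_expression_model()
        female, male = simulate_libraries(
            genome, features, model, config.n_reads_per_sex,
            _subseed(config.seed, 1), unmappable_fraction=config.unmappable_fraction,
        )
        xio.write_genome_fasta(_out("genome", "genome.fa"), genome)
        xio.write_bed_features(
            _out("features_bed", "features.bed"), _out("features_classes", "features_classes.tsv"),
            features, header,
        )
        xio.write_variants(_out("variants", "variants.tsv"), variants, header)
        xio.write_fastq(_out("reads_female", "reads_female.fastq"), female)
        xio.write_fastq(_out("reads_male", "reads_male.fastq"), male)
        log.info("simulate done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        t0 = _stage("map")
        index = build_index(genome)
        results = {
            "female": map_reads(female, index, max_hits=config.max_hits),
            "male": map_reads(male, index, max_hits=config.max_hits),
        }
        for sex, res in results.items():
            xio.write_hits(_out(f"hits_{sex}", f"hits_{sex}.tsv"), fractional_counts(res), header)
        log.info("map done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage map failed: {exc}") from exc

    try:
        t0 = _stage("annotate")
        summaries = []
        for sex in ("female", "male"):
            res = results[sex]
            assignments = assign_classes(res, features, config.min_overlap_frac)
            summary = summarize(res, assignments, sex)
            sec = secondary_annotation(res, assignments, features, config.min_overlap_frac)
            summary.secondary_fractions = secondary_fractions(res, sec)
            summaries.append(summary)
        xio.write_summary(_out("summary", "classification_summary.tsv"), summaries, header)
        log.info("annotate done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage annotate failed: {exc}") from exc

    try:
        t0 = _stage("screen")
        records = build_count_records(
            features, results["female"], results["male"], config.min_overlap_frac
        )
        xio.write_counts(_out("counts", "counts.tsv"), records, header)
        result = screen(records, config.screen_params)
        xio.write_screen_table(_out("screen_female_zero", "screen_female_zero_male.tsv"),
                               result.female_zero_male, header)
        xio.write_screen_table(_out("screen_female_up", "screen_female_up.tsv"),
                               result.female_up, header)
        xio.write_screen_table(_out("screen_male_up", "screen_male_up.tsv"),
                               result.male_up, header)
        log.info("screen done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage screen failed: {exc}") from exc

    try:
        t0 = _stage("imprint")
        calls = verify_imprinting(
            variants, config.imprint_mode, config.f1_transcripts_per_cross,
            _subseed(config.seed, 2),
        )
        xio.write_imprint_calls(_out("imprint_calls", "imprint_calls.tsv"), calls, header)
        log.info("imprint done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage imprint failed: {exc}") from exc

    try:
        t0 = _stage("stats")
        qpcr_tables = {}
        stats_results = []
        for gi, (gene, f_ratio, m_ratio) in enumerate(QPCR_PANEL):
            df = simulate_qpcr(
                f_ratio, m_ratio, config.qpcr_cv, config.qpcr_n_reps,
                _subseed(config.seed, 100 + gi),
            )
            qpcr_tables[gene] = df
            stats_results.append(
                sex_bias_test(
                    df[df.sex == "female"].value.tolist(),
                    df[df.sex == "male"].value.tolist(),
                    alpha=config.alpha,
                    gene_id=gene,
                )
            )
        xio.write_qpcr_replicates(_out("qpcr_replicates", "qpcr_replicates.tsv"),
                                  qpcr_tables, header)
        xio.write_stats_results(_out("stats", "sex_bias_stats.tsv"), stats_results, header)
        log.info("stats done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(f"stage stats failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "genome": genome,
        "features": features,
        "variants": variants,
        "mapping": results,
        "summaries": summaries,
        "count_records": records,
        "screen": result,
        "imprint_calls": calls,
        "stats": stats_results,
        "manifest": manifest,
    }
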
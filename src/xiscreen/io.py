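"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython's SeqIO; tables are TSV via pandas. All
writers put a comment header (``# key: value`` lines) with the tool version,
seed and parameters on top of machine tables; readers skip ``#`` lines.
Intervals are BED-convention 0-based half-open; GFF3 (1-based closed) is
converted on read.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotation import ClassificationSummary
from .mapping import WeightedHit
from .model import ALL_CLASSES, AnnotationFeature, GenomeRef, SmallRNARead, StrainVariant
from .rflp import ImprintCall
from .screen import ScreenHit, round_half_up
from .stats import SexBiasResult

EM_DASH = "–"  # zero read counts in human-facing screen tables


class FileFormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------- sequences

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; empty file yields an empty list."""
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_fasta(path, records: Iterable[tuple[str, str]], header: Optional[dict] = None) -> None:
    # FASTA has no comment syntax; header metadata goes in the id-less
    # description of a sidecar-free world — omitted here, recorded in the
    # manifest instead.
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path) -> list[SmallRNARead]:
    """Reads from FASTQ; library sex is parsed from an ``sex=`` tag in the
    description when present, defaulting to female."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            sex = "female"
            for token in rec.description.split():
                if token.startswith("sex="):
                    sex = token[4:]
            out.append(SmallRNARead(rec.id, str(rec.seq).upper(), sex))
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(path, reads: Iterable[SmallRNARead]) -> None:
    """Dummy-quality FASTQ ('I' per base), one record per read."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} sex={r.library_sex}\n{r.sequence}\n+\n{'I' * len(r)}\n")


def write_genome_fasta(path, genome: GenomeRef) -> None:
    write_fasta(path, genome.chromosomes.items())


# ----------------------------------------------------------------- features

def write_bed_features(bed_path, class_tsv_path, features: Sequence[AnnotationFeature],
                       header: Optional[dict] = None) -> None:
    with open(bed_path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t.\t{f.strand}\n")
    with open(class_tsv_path, "w") as fh:
        _write_header(fh, header)
        fh.write("feature_id\tclass\n")
        for f in features:
            fh.write(f"{f.feature_id}\t{f.class_label}\n")


def read_bed_features(bed_path, class_tsv_path,
                      genome: Optional[GenomeRef] = None) -> list[AnnotationFeature]:
    """BED intervals joined with a feature_id -> class TSV.

    When a genome is supplied, intervals are validated against chromosome
    bounds.
    """
    classes = _read_table(class_tsv_path).set_index("feature_id")["class"].to_dict()
    features = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FileFormatError(f"{bed_path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, fid, _, strand = cols[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FileFormatError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if fid not in classes:
                raise FileFormatError(f"{bed_path}:{lineno}: feature {fid!r} missing from class table")
            cls = classes[fid]
            if cls not in ALL_CLASSES:
                raise FileFormatError(f"{class_tsv_path}: unknown class label {cls!r}")
            if end_i <= start_i:
                raise FileFormatError(f"{bed_path}:{lineno}: end <= start")
            if genome is not None:
                if chrom not in genome.chromosomes:
                    raise FileFormatError(f"{bed_path}:{lineno}: unknown chromosome {chrom!r}")
                if end_i > len(genome.chromosomes[chrom]):
                    raise FileFormatError(f"{bed_path}:{lineno}: interval beyond chromosome end")
            features.append(AnnotationFeature(fid, cls, chrom, start_i, end_i, strand))
    return features


def read_gff3_features(path, genome: Optional[GenomeRef] = None) -> list[AnnotationFeature]:
    """GFF3 with a ``class=`` attribute; 1-based closed coordinates are
    converted to 0-based half-open on read."""
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    except Exception as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    features = []
    for f in db.all_features():
        cls_values = f.attributes.get("class")
        if not cls_values:
            raise FileFormatError(f"{path}: feature {f.id!r} lacks a class= attribute")
        cls = cls_values[0]
        if cls not in ALL_CLASSES:
            raise FileFormatError(f"{path}: unknown class label {cls!r}")
        start0, end0 = f.start - 1, f.end
        if genome is not None and end0 > len(genome.chromosomes.get(f.seqid, "")):
            raise FileFormatError(f"{path}: feature {f.id!r} beyond chromosome end")
        features.append(AnnotationFeature(f.id, cls, f.seqid, start0, end0, f.strand))
    return features


# ----------------------------------------------------------------- variants

def write_variants(path, variants: Sequence[StrainVariant], header: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("locus\tflank5\tflank3\tb6_allele\tjf1_allele\tkind\n")
        for v in variants:
            fh.write(f"{v.locus}\t{v.flank5}\t{v.flank3}\t{v.b6_allele}\t{v.jf1_allele}\t{v.kind}\n")


def read_variants(path) -> list[StrainVariant]:
    df = _read_table(path)
    return [
        StrainVariant(r.locus, r.flank5, r.flank3, r.b6_allele, r.jf1_allele, r.kind)
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------- hits

def write_hits(path, weighted_hits: Sequence[WeightedHit], header: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("read_id\tchrom\tstart\tend\tstrand\tweight\n")
        for h in weighted_hits:
            fh.write(f"{h.read_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{float(h.weight):.6g}\n")


# ----------------------------------------------------------------- summary

def write_summary(path, summaries: Sequence[ClassificationSummary],
                  header: Optional[dict] = None) -> None:
    """Classification summary, one column per library, fixed row order."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("row\t" + "\t".join(s.sex for s in summaries) + "\n")
        for i, (row_name, _) in enumerate(summaries[0].rows()):
            vals = [str(s.rows()[i][1]) for s in summaries]
            fh.write(f"{row_name}\t" + "\t".join(vals) + "\n")
        for frac_name in ("repeat", "tRNA", "unannotated"):
            vals = [f"{s.secondary_fractions.get(frac_name, 0.0):.4f}" for s in summaries]
            fh.write(f"only_genomic_{frac_name}_fraction\t" + "\t".join(vals) + "\n")


# ------------------------------------------------------------ screen tables

def _fmt_reads(value: float, decimals: int, human: bool) -> str:
    if value == 0 and human:
        return EM_DASH
    return f"{round_half_up(value, decimals):.{decimals}f}"


def write_screen_table(path, hits: Sequence[ScreenHit], header: Optional[dict] = None,
                       human: bool = True, reads_decimals: int = 2,
                       ratio_decimals: int = 3) -> None:
    """One candidate list in the published column order.

    ``human=True`` renders zero read counts as an en-dash, as in the
    published tables; machine tables keep 0.
    """
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("RNA_ID\tRNA_TYPE\tFemale_READS\tMale_READS\tM/F_READS\tchromosome\n")
        for h in hits:
            rec = h.record
            ratio = (
                f"{h.ratio.value:.{ratio_decimals}f}"
                if h.ratio.value is not None
                else h.ratio.marker.value
            )
            fh.write(
                f"{rec.feature_id}\t{rec.rna_type}\t"
                f"{_fmt_reads(rec.female_reads, reads_decimals, human)}\t"
                f"{_fmt_reads(rec.male_reads, reads_decimals, human)}\t"
                f"{ratio}\t{rec.chromosome}\n"
            )


def write_counts(path, records, header: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("feature_id\trna_type\tfemale_reads\tmale_reads\tfemale_rpkm\tmale_rpkm\tchromosome\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.rna_type}\t{r.female_reads:.6g}\t{r.male_reads:.6g}\t"
                f"{r.female_rpkm:.6g}\t{r.male_rpkm:.6g}\t{r.chromosome}\n"
            )


# ----------------------------------------------------------- imprint calls

def write_imprint_calls(path, calls: Sequence[ImprintCall], header: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("locus\tverdict\tprovisional\tobserved_alleles\n")
        for c in calls:
            obs = ";".join(
                f"{cr.maternal_strain}x{cr.paternal_strain}={allele}"
                for cr, allele in c.observations
            )
            fh.write(f"{c.locus}\t{c.verdict}\t{str(c.provisional).lower()}\t{obs}\n")


# -------------------------------------------------------------------- stats

def write_qpcr_replicates(path, tables: dict[str, pd.DataFrame],
                          header: Optional[dict] = None) -> None:
    """Long-format replicate TSV: gene, sex, replicate, value."""
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("gene\tsex\treplicate\tvalue\n")
        for gene, df in tables.items():
            for r in df.itertuples():
                fh.write(f"{gene}\t{r.sex}\t{r.replicate}\t{r.value:.6g}\n")


def read_qpcr_replicates(path) -> pd.DataFrame:
    return _read_table(path)


def write_stats_results(path, results: Sequence[SexBiasResult],
                        header: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("gene\tfemale_mean\tfemale_sd\tmale_mean\tmale_sd\tt\tdf\tp\tsignificant\n")
        for r in results:
            star = "*" if r.significant else ""
            fh.write(
                f"{r.gene_id}\t{r.female_mean:.6g}\t{r.female_sd:.6g}\t"
                f"{r.male_mean:.6g}\t{r.male_sd:.6g}\t{r.t_statistic:.6g}\t{r.df}\t"
                f"{r.p_value:.6g}\t{star}\n"
            )


# ------------------------------------------------------------------ helpers

def _write_header(fh, header: Optional[dict]) -> None:
    fh.write(f"# xiscreen {__version__}\n")
    for k, v in (header or {}).items():
        fh.write(f"# {k}: {v}\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"flank5": str, "flank3": str,
                                                           "b6_allele": str, "jf1_allele": str})
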
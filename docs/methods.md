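# Methods

## Study design being modelled

Female mouse embryos carry one maternal and one paternal X; males carry a
single maternal X. A gene expressed exclusively from the paternal X (Xp) is
therefore female-specific by construction. The pipeline models the resulting
two-stage screen: (i) compare small-RNA abundance between sexed libraries and
keep strongly female-biased candidates; (ii) verify parent-of-origin
expression with strain-diagnostic polymorphisms in reciprocal F1 crosses
between C57BL/6 (B6) and JF1 mice. The sex of each X haplotype is fixed by
Mendelian rules encoded as invariants: an XY male's X is always maternal, and
the F1 father in the B6♀ × (JF1 × B6)♂ cross contributes a JF1 X because he
received his X from his JF1 mother.

## Mapping and counting

Reads are 18–26 nt; only perfect, full-length matches count. The mapper seeds
on forward-strand 18-mers and verifies the full query on both strands, which
for queries of 18–26 nt retrieves *all* exact occurrences; minus-strand hits
are reported in forward coordinates. Unmapped reads (no perfect hit,
non-ACGT symbols, off-range length) are excluded from every downstream count;
they constitute the gap between total and genome-mapped reads.

Multi-mapping policy: a read with *k* hits contributes weight 1/*k* per hit
(× its multiplicity). Weights are carried as exact rational numbers
(`fractions.Fraction`) so the sum of all weights equals the mapped read count
exactly, not approximately; floats appear only when tables are written.
Reads hitting more than 200 loci (configurable) are treated as repeat-derived:
they stay in the genome-mapped totals and the only-genomic/repeat summary but
are excluded from per-feature counting.

## Annotation rules

A hit is assigned a feature when ≥ 50 % of the read length overlaps the
feature interval (configurable) and, for ncRNA classes, strands agree (mature
miRNAs are stranded). A read may carry several class labels — a read inside a
mature miRNA is also inside its hairpin and possibly a host gene — and is
counted once in each class row, so the genome-mapped total need not equal
"total ncRNA" plus "only genomic"; "total ncRNA" is defined as the number of
reads with ≥ 1 ncRNA label, which need not equal the column sum either.
Weights are split across genomic *loci* only, never across overlapping
annotations of one locus.

Reads with no ncRNA label are "only genomic" and re-annotated against repeat
and tRNA intervals. This secondary pass is strand-agnostic (degradation
fragments have no meaningful polarity) and breaks repeat/tRNA ties in favour
of repeat; both choices are configurable and neither is dictated by the
modelled protocol, which is silent on them.

## Screen semantics

Filters operate on fractional read counts, not RPKM (the selection rules are
stated in reads); RPKM = count / ((length/1000) × (mapped/10⁶)) is reported
alongside. Rules, with strictness chosen to match the stated wording:

* zero class — male = 0 **and** female **>** 10 reads;
* female up — male > 0, female/male **>** 10-fold, female **≥** 20 reads;
* male up — symmetric.

Records with zero female and positive male reads receive a `ZERO_FEMALE`
marker and are not listed (the modelled screen defines a zero-read block only
in the female direction). Ratios are computed on unrounded counts and then
rounded **half-up** to 3 decimals (banker's rounding would flip edge cases
such as 0.0125); read counts print at 2 decimals, zeros render as an en-dash
in the human-facing tables and as 0 in machine tables. Zero-class rows sort
by descending female reads, fold-change lists by ratio.

## Allelic genotyping and parent-of-origin inference

Enzyme motifs are IUPAC-degenerate (built-ins: HpyCH4III `ACNGT`, StyI
`CCWWGG`; both are their own reverse complements, so one-strand scanning
suffices). Digestion cuts at every site (default offset: end of the
recognition sequence) and always conserves total length. Genotyping calls an
allele present when its predicted digest — after removing fragments below a
10 nt gel-detection floor — is a sub-multiset of the observed fragments;
both alleles → biallelic, neither → ambiguous, identical predictions →
uninformative. Because calls rest on presence/absence of cutting, they are
invariant to the cut offset. Insertion polymorphisms (B6 `AAA` vs JF1 `AA`)
are called by exact window matching against the two allele amplicons.

One StyI ambiguity is resolved in favour of the enzyme's motif: `CCAAGG`
(assigned to JF1 here) contains a CCWWGG site and `CCAAAG` (B6) does not, so
in the synthetic variant the JF1 allele carries the cut site.

Parent-of-origin: over informative crosses, a locus is *paternal* when every
observed allele equals that cross's paternal X haplotype, *maternal* in the
mirror case, *biallelic* if both alleles appear, and *inconsistent* when the
allele tracks strain rather than parent. Exhaustive enumeration of the four
reciprocal two-cross outcomes yields exactly one paternal, one maternal and
two inconsistent verdicts. A verdict from a single cross is flagged
provisional.

## Expression statistics

Relative expression is the per-replicate ratio of target to housekeeping
reference copies. Sex differences use a pooled-variance ("Student's")
two-sample two-tailed t-test — pooled rather than Welch because that is the
named test of the modelled protocol — with df = n₁ + n₂ − 2, α = 0.01 and
n = 3 replicates by default. Reported dispersion is the sample SD (n − 1);
the modelled protocol's wording is ambiguous between SD and SEM, and sample
SD was chosen. Zero pooled variance is degenerate: equal means give p = 1,
unequal means p = 0, both flagged.

## Synthetic-data generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Genome**: one 50 kb autosome, a 50 kb X and a 4 kb mitochondrial contig
  of uniform random sequence (minimum 10 kb for the nuclear chromosomes).
  Deterministic given the seed.
* **Annotations**: ≥ 1 feature of every ncRNA class; a 200 nt repeat unit
  copied to three autosomal and two X-linked loci (real multi-mappers); two
  tRNAs; and on the X a 1.2 kb host-gene interval containing two hairpins
  whose mature miRNAs (22 and 23 nt) lie adjacent — the clustered,
  host-intron arrangement of the screen's real candidates.
* **Expression**: per-feature read counts are Poisson at the model means.
  The planted X-linked matures use the observed female counts of the real
  candidates (46 and 38) with male means of exactly 0 (enforced by the
  paternal × X-linked invariant); an abundant autosomal control miRNA
  (300/300) dominates the ncRNA fraction; one snoRNA is female-biased
  (96/0.8) and one snRNA male-biased (0.7/70) so all three candidate lists
  are populated. Poisson counts and lognormal qPCR noise are the simplest
  standard models for count and ratio data; the modelled study states
  neither.
* **Background**: 90 % of the nominal library size is degradation background
  (the observed "only genomic" share), split 0.5/0.2/0.3 between repeat,
  tRNA and intergenic reads (making repeat+tRNA ≈ 70 % of the only-genomic
  fraction, as observed). Background reads are sampled from intergenic space
  only: a fragment overlapping an ncRNA would be classified as that ncRNA,
  and intergenic sampling keeps the male counts of planted female-only
  features exactly zero, which the recovery guarantee relies on. An optional
  unmappable fraction (pipeline default 0.08, the observed unmapped share)
  plants reads verified absent from the genome.
* **Variants**: two SNVs that create/destroy degenerate enzyme sites
  (HpyCH4III and StyI contexts) and one `AAA`→`AA` insertion, each with
  60 nt flanks taken from the genome (the reference carries the B6 allele).
* **qPCR**: multiplicative lognormal noise with unit mean and CV 0.1 by
  default (σ² = ln(1+cv²), μ = −σ²/2); cv = 0 reproduces the true ratios
  exactly.

What the generator does **not** emulate: sequencing error (454 homopolymer
artefacts), miRNA end-heterogeneity and editing, amplification bias,
non-uniform coverage along features, partial escape from silencing (male
means of imprinted X genes are exactly 0, whereas real males show weak
expression at high PCR cycles), and realistic genome repeat structure.
Passing tests therefore demonstrate the correctness of the *computational*
semantics — mapping, counting, filtering, genotyping logic, inference and
calibration — not robustness to those biological and technical artefacts.

## Problem sizes and numerical choices

Default pipeline runs use 104 kb of genome and 5 000 nominal reads per sex,
and the mapper-oracle and end-to-end checks run on 100 kb genomes, 10³ reads
or 20 independent seeds — sizes chosen so the whole suite exercises every
path at desk scale while remaining statistically decisive (the planted means
of 46 and 38 leave Poisson mass below the zero-class threshold of order
10⁻⁷ per feature per run). Ratio rounding is decimal half-up on the shortest
decimal representation of the double; all randomness flows from explicit
integer seeds through `numpy.random.default_rng`, and repeated runs with one
seed are byte-identical (output headers exclude the output directory for
this reason).

## Known limitations

* The mapper is exact-match only by design; no mismatch/indel alignment.
* RFLP genotyping assumes noiseless fragment observation above the detection
  floor; band intensities are not modelled, so allele *ratios* cannot be
  quantified, only presence/absence.
* The screen applies no dispersion model or multiple-testing control — the
  modelled protocol validated candidates by qRT-PCR instead, and the package
  mirrors that.
* Strain alphabet is fixed to {B6, JF1}.
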
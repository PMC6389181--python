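# Methods

## Scope and model

`cisnat` analyses strand-specific RNA-seq of stress time-courses at
*single-gene loci*: genomic loci occupied by exactly one annotated gene, the
only places where reads in the opposite transcriptional orientation can be
attributed unambiguously to a *cis*-natural antisense transcript. The
pipeline is count-based throughout: no transcript assembly, no antisense
boundary inference (antisense signal is reported relative to the annotated
sense transcript it overlaps), and no dispersion-modelling GLMs — the
differential test is the classical G-test on pooled counts.

## Quality trimming

Reads are trimmed from both the 5′ and 3′ ends until a stretch of
`stretch` (default 3) consecutive bases with quality ≥ `q_threshold`
(default Phred 15) appears at each end. We read this rule as: keep the
contiguous subread from the start of the *first* qualifying run to the end
of the *last* qualifying run. This is the only interpretation under which
both ends are trimmed symmetrically and a qualifying stretch "appears" at
each end; it implies interior low-quality bases are retained, and the
trimmed read, when non-empty, has length ≥ `stretch` with fully
high-quality terminal runs. Trimmed reads shorter than `min_length`
(default 20 bp, configurable) are discarded to avoid unalignable fragments.
The implementation is verified against an oracle that enumerates every
(prefix, suffix) cut pair and keeps the maximal window whose terminal runs
qualify.

## Locus catalog

Overlap is decided on full gene spans (union of transcript spans per gene)
with a ≥1 bp intersection threshold, not at exon level: the analysis
reasons about loci, and an intronic antisense signal is still antisense.
Opposite-strand overlaps are always excluded. Same-strand overlaps are
excluded by default as well — attribution of sense counts between two
co-oriented overlapping genes is ambiguous — but `exclude_same_strand=False`
restores the strict opposite-orientation-only criterion. Quantification is
reported per transcript; a multi-transcript gene contributes one count row
per transcript with the locus-level counts, and each transcript's own exon
length is used as its RPKM denominator.

## Quantification

A read is counted when its alignment interval overlaps an eligible locus
span by ≥1 bp, it is uniquely mapped, and it overlaps no second eligible
locus (such straddling reads are discarded to prevent double counting).
Uniqueness is taken from the `NH` tag when present (`NH == 1`), with a MAPQ
threshold as the configurable alternative. Strandedness defaults to
`forward` (read orientation = transcript orientation); `reverse` flips every
assignment, and the flip maps each sense count to the antisense cell
exactly. RPKM = 10⁹·C/(N·L) with N the number of unique alignments in the
sample and L the exon length in bp; L of the annotated transcript is used
for both strand classes, since the antisense transcript's own extent is
unknown.

## Differential expression

Replicate counts are summed into one pooled count and one pooled library
size per side of a contrast, and each (transcript, strand class) is tested
with the G-test on the 2×2 table of (feature reads, remaining reads) ×
(treated, baseline); G = 2·Σ O·ln(O/E) with 0·ln(0/E) ≡ 0, referred to χ²
with 1 df. A table with a zero margin carries no information and returns
(G = 0, p = 1). Pooling is the construction the two-sample proportion test
supports; it is also the reason for the calibration caveat below. The
baseline is the 0 h group of the same tissue and condition (the
untreated-sample convention); a time-matched control mode is available via
`baseline_condition`.

P-values are adjusted with Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest.multipletests`) within each (contrast, strand
class) family — sense transcripts and antisense transcripts are separate
analyses. The default significance threshold is FDR < 0.01; 0.001 is
available by parameter.

Fold changes are pseudocounted ratios of replicate-mean RPKM,
fc = (RPKM_t + c)/(RPKM₀ + c) with c = 1.0 by default. The pseudocount of 1
is the convention under which a zero-baseline locus reports fc = RPKM_t + 1;
it also regularises low-expression ratios. Calls are significance-driven
(`fc_floor` = 1): up iff q < α and fc > 1; a floor of 5 reproduces a
">5-fold" reporting filter. Replicate QC computes the minimum pairwise
Pearson r between replicate RPKM vectors per sample group and flags groups
with r ≤ 0.9 (zero-variance vectors leave r undefined and fail); flagged
groups are reported, never silently dropped.

## Classification and overlap statistics

Loci with antisense called up are partitioned by their sense call:
up → *upregulated*, down → *downregulated*, and not significant at the
configured FDR in either direction → *invariable*. "Invariable" has no
separate numeric definition — non-significance is the only criterion the DE
machinery itself provides. The groups partition the antisense-up set by
construction. Overlap statistics enumerate all 2ᵏ−1 exclusive Venn regions
of k named transcript sets; shared fractions are 100·|A ∩ ∪others|/|A|,
rounded half-up to one decimal (the reporting convention for percentages
throughout). GO tabulation is a plain distribution over a user-supplied
transcript→category mapping (a transcript with k categories counts in all
k; unmapped members are tallied as "unannotated"); no enrichment statistics
are computed.

## Synthetic data

The generator emulates a multi-condition, multi-timepoint stranded
experiment: isolated single-gene loci plus planted opposite-strand and
same-strand overlapping gene pairs (to exercise catalog exclusion), a
(tissue × condition × time × replicate) design, and per-locus sense and
antisense counts drawn NB2 (variance = m + φ·m²; φ = `dispersion`,
0 → Poisson) around baseline means scaled by per-(locus, class, condition,
time) effect multipliers. Defaults mirror the emulated study design: 75 bp
single-end reads, 0/1/12/24 h timepoints, ≥2 replicates, dispersion 0.1,
antisense baseline (20) well below sense baseline (100) since antisense
transcription is typically the minor signal. Reads are placed uniformly
within the locus span and written as per-sample SAM; with a multimapper
fraction of 0, quantification recovers the simulated counts *exactly*
(round-trip identity), which the tests assert. The generator does not
simulate sequencing error, adapters, rRNA contamination, splicing or
inter-locus background reads — so passing tests demonstrate the counting,
testing and classification logic, not robustness to alignment artefacts.
Realised library sizes are the per-sample count totals.

## Calibration caveat: the G-test under replicate overdispersion

Under its own sampling assumption (binomial counts), the G-test is well
calibrated: on 5,000 null tables with expected counts ≥5 the p-value
distribution's KS distance from uniform is ~0.03. Under biological
replication it is not: pooling NB2 replicates with dispersion φ inflates the
variance of the pooled count by a factor ≈ 1 + φ·m relative to binomial, so
null G statistics are stretched χ² and small p-values are grossly
over-produced (at m = 100 and φ = 0.1 the inflation is ≈11×). In the
200-locus recovery experiment this makes sensitivity for strong (10×)
effects essentially perfect while a substantial fraction of null loci are
also called significant at FDR < 0.01 — the acceptance suite measures and
reports exactly this behaviour rather than hiding it. This anti-
conservativeness is inherent to proportion tests applied to replicated
RNA-seq and is the reason dispersion-modelling NB GLMs exist; those are
deliberately out of scope here, because the G-test *is* the method being
implemented. Interpretation guidance: significance counts from this
pipeline are comparable across conditions analysed the same way, but are
not calibrated false-discovery rates in the presence of biological
replicate variability.

## Numerical and determinism choices

Problem sizes in tests and the acceptance script (200-locus recovery
experiment, 1,000-table oracle sweeps, 5,000-table calibration) are chosen
to make Monte-Carlo tolerances tight while keeping the full suite in the
tens of seconds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng` with distinct stream keys per stage; reruns of
the generator and the pipeline are byte-identical (output paths in the
design table are relative for this reason, and only `run.log` carries a
timestamp). Percentages use half-up rounding, not banker's rounding.
Degenerate inputs are errors, not silent results: zero exon length, a zero
library with nonzero counts, an alignment on an unknown chromosome, a
transcript in the antisense-up set missing from the sense results.
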
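# Methods

This note documents the models the package implements, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices made where more than one reading was defensible.

## Small-RNA read assignment

A trimmed read is scored against every mature miRNA at every ungapped
offset. The overlap at an offset is the intersection of the read span and
the miRNA span; a candidate requires overlap ≥ `min_overlap` (default 17 nt)
with zero mismatches inside it, and its score is the overlap length. The
read is assigned iff a unique miRNA attains the maximal score.

Design choices:

* **Ambiguity.** When two or more distinct miRNAs tie at the maximal score
  (common for miRNA families differing at one terminal base), the read is
  left uncounted (`unassigned_ambiguous`) rather than multi-counted, so
  per-sample column sums equal the number of assigned reads. A
  `count_all_best` mode exists for sensitivity analysis and deliberately
  breaks that conservation.
* **Overhangs.** Read bases extending beyond a miRNA's termini are ignored,
  not counted as mismatches: isomiRs with shifted or untemplated ends still
  match over their templated core, which is what the overlap criterion
  scores.
* **Strandedness.** No reverse-complement search by default; small-RNA
  protocols are stranded. A flag enables it for unstranded input.
* **Adapter trimming** is by exact match of the adapter's first 8 nt
  (configurable); trimmed inserts shorter than `min_overlap` are discarded.
  Published small-RNA trimmers differ in details that do not matter at the
  mismatch-free exact-overlap assignment stage.
* **Expression filter.** Default retains a miRNA when any sample reaches
  ≥ 10 reads (`max_per_sample`); `strict_gt` (> 10) and `total` modes are
  provided because both inclusive and strict phrasings circulate for this
  filter and the aggregation level (per sample vs total) is a choice.

The implementation is checked against an exhaustive per-base brute-force
scorer (independent code path) on a thousand random read/reference
instances, and for order-independence of the tie rule.

## Count-based differential expression

* **Upper-quartile normalization.** The size factor of a sample is the 75th
  percentile (linear-interpolation / type-7 quantile, fixed for
  reproducibility) of its counts over features that are nonzero in at least
  one sample; values are divided by the size factor and rescaled by the
  geometric mean of the size factors so the matrix keeps its overall scale.
  After normalization all samples share the same upper quartile.
* **Fold change.** log2((mean_case + c)/(mean_ctrl + c)) with pseudocount
  c = 1 by default — zeros do occur in miRNA counts at realistic depths.
  With c > 0 the scale-invariance of downstream results under a global
  rescaling of raw counts is approximate (exact as c → 0 or counts → ∞).
* **The test.** The default mode is a two-tailed Welch *t* on
  log2(normalized + c) between groups. Welch rather than pooled variance:
  group sizes of 5–6 with no variance model argue against assuming equal
  variances. A second mode, `fc_contrast`, implements the literal
  "intra- vs inter-condition" comparison: a two-sample *t* of the
  case-vs-control pairwise log2 ratios against the pooled within-group
  pairwise log2 ratios. Both modes report the pairwise-ratio diagnostics
  (intra spread, inter mean). The sentence describing the original
  procedure under-determines the statistic; exposing both readings, with
  the plain *t*-test as default, is the package's resolution.
* **Degenerate features.** Zero variance in both groups with equal means
  gives p = 1 by convention; with unequal means the p → 0 limit is reported
  as the smallest positive float and logged.
* **BH correction** is implemented directly from the step-up definition
  (order-preserving, capped at 1) and is cross-checked in the tests against
  both a brute-force evaluation of the definition and statsmodels.
* **Selection** is strict on both sides: |log2FC| > 1 and p_adj < 0.05.

Calibration: under a 5v5 negative-binomial global null the raw p < 0.05
fraction sits slightly below nominal (≈ 0.040–0.045 across seeds) — the
*t*-test on log counts at n = 5 is mildly conservative — within the exact
binomial 99% band around 0.05 at the sizes tested (2,000 features).

## A-to-I editing

* **Level**: edited/(edited + unedited) reads at a site; undefined at zero
  coverage.
* **Indices**: AEI (Alu-class sites) and REI (recoding-class sites) are
  coverage-weighted pooled ratios Σ_k edited_k / Σ_k total_k over covered
  sites of the class — the weighted-average form standard for Alu editing
  indices. An unweighted per-site mean mode exists for sensitivity. The
  index is bounded by the min and max contributing site levels and is
  invariant to uniform coverage scaling.
* **Site filters**: a recoding site is tested only if covered (total > 0)
  in ≥ 3 samples of each group and its median per-sample level over all
  samples pooled is strictly > 0.1. The pooling choice (not per-group) and
  strictness follow the "median higher than 0.1" reading; both knobs are
  configurable. Note that genuinely asymmetric sites (e.g. near-zero in
  controls, ~0.15 in cases) can fail the pooled-median filter even when the
  group difference is real; with patient data the filter operates on
  observed cohorts, and the same behaviour appears in simulation.
* **Differential editing**: per retained site, a two-tailed Welch *t* on
  raw per-sample levels (no transform by default; an arcsine-sqrt option
  exists but plain levels are the stated procedure), BH across retained
  sites, significance at p_adj ≤ 0.1 (inclusive, matching "FDR = 0.1").
  Group means are unweighted means of per-sample levels — matching how
  per-group mean editing levels are conventionally tabulated — and the edit
  difference is control − case, so positive means lower editing in disease.
* **Group index comparison**: Welch *t* per index class, BH across classes,
  with Tukey box-plot summaries (whisker fences at Q3 + 1.5·IQR and
  Q1 − 1.5·IQR; values outside are listed as outliers).

## RT-qPCR

* Replicate Cts are arithmetically averaged per (sample, gene) before
  anything else; no outlier-replicate rejection by default.
* **geNorm M**: for candidates j, k the pairwise variation V_jk is the
  sample SD of Ct_j − Ct_k (shift-invariant); M_j is the mean over k ≠ j.
  Ranking by iterative exclusion of the highest-M gene until a final pair
  remains; geNorm cannot order that pair, so it is listed in ascending
  full-set M. Checked against a brute-force pairwise-SD evaluation.
* **NormFinder-style stability** re-implements the published
  variance-decomposition idea rather than the applet bit-for-bit: Cts are
  sample-centered (subtracting each sample's mean over candidates, removing
  sample loading), then per gene ρ = mean over groups of
  (|group bias| + √(within-group variance / n_group)); larger is less
  stable. With small cohorts this ranking is noisy for the stable genes
  (the bias term is noise-driven when true bias is zero); the consensus
  with geNorm makes the final selection robust in practice.
* **Consensus selection**: genes present in both methods' top-k are taken
  first (in geNorm order), remaining slots filled by geNorm rank — the
  merge rule the original selection of 3 of 5 candidates did not specify,
  so it is fixed here and documented.
* **ΔΔCt**: per sample, ΔCt = Ct_target − mean(Ct of selected
  housekeepers); ΔΔCt = ΔCt − mean(ΔCt over control samples); the reported
  quantity is log2 relative expression −ΔΔCt (i.e. log2 of 2^−ΔΔCt). This
  is the only reading under which up-regulated targets have positive
  values; "log2(ΔΔCt)" as sometimes printed is not a well-defined quantity
  for negative ΔΔCt. Control-group mean is 0 by construction (calibrator
  identity, exact to machine precision); adding a constant to every
  housekeeper Ct changes nothing.

## Synthetic data: what it emulates, and what it does not

Generators return the planted truth alongside the data, so recovery checks
never re-derive truth from generator internals.

* **Reads**: (3'-trimmed miRNA)(adapter)(random padding) at 50 nt with
  isomiR 3' trimming of 0–3 nt (probabilities 0.85/0.10/0.04/0.01) and
  optional per-base substitution noise; constant Q40 qualities. Family
  pairs differ at exactly the last base so they share a ≥ 17-nt block and
  provably exercise tie handling. Not emulated: realistic quality-score
  profiles, indels, 5' end variation, ligation bias.
* **Counts**: negative binomial with var = μ + φμ² (φ = `nb_dispersion`,
  default 0.1; φ = 0 degenerates to Poisson), feature means log-uniform on
  (20, 2000) by default, lognormal per-sample depth factors (sd 0.25) so
  upper-quartile normalization has real work to do, DE effects applied
  multiplicatively to case means with alternating sign. Not emulated:
  mean-dispersion trends, outlier counts, correlated features.
* **Editing pileups**: per-sample site level ~ Beta(mα, (1−m)α) around the
  group mean m with concentration α (default 50; degenerate at m ∈ {0,1}),
  Poisson coverage, binomial edited counts, optional dropout to zero
  coverage. Group means in the analyses use the published per-site
  control/case means (e.g. 0.972 vs 0.918 at a GRIA2-like Q/R site) so
  simulated effect sizes match reported magnitudes. Not emulated:
  correlated sites, mapping artefacts, allele-specific coverage.
* **Ct tables**: Ct = gene base (uniform 18–30 cycles) + sample loading
  (sd 0.5) + per-(sample,gene) stability noise (the housekeeper grading) −
  group effect (case targets only) + replicate noise (sd 0.1), triplicates,
  9 samples per group by default (an enlarged two-cohort design). A target
  effect of g cycles yields an intended case-group mean log2 relative
  expression of +g. Not emulated: amplification-efficiency differences,
  plate effects, non-detects.

Because the generators match the distributional assumptions of the tests
(negative binomial counts, beta-binomial levels, Gaussian Ct noise),
passing recovery and calibration checks demonstrates correctness of the
implementations under their assumed models — not robustness to the ways
real patient data violate those models (outliers, batch structure,
confounding, uncontrolled RNA quality).

## Problem sizes and determinism

The test-suite and driver simulations use 2,000 features at 5v5 for DE
calibration/power, 14 recoding sites at 6v6 with coverage 1,000 and
concentration 500 for editing recovery, ~1,000 random instances for the
assignment oracle, and 9v9 triplicate Ct tables — sizes at which the
Monte-Carlo error of every asserted quantity is far inside its tolerance
while the whole suite runs in seconds. All randomness flows from explicit
seeds (`numpy.random.default_rng`); identical seeds give byte-identical
outputs.

## Known limitations

* The assignment scorer is exhaustive over offsets (no indexing); it is
  meant for references of 10²–10⁴ mature sequences, not genome-scale
  search.
* The headline patient-cohort findings of the motivating study (thousands
  of DE genes, specific deregulated miRNAs, 14/1,585 differential sites,
  an REI decrease) depend on unreleased sequencing data; this package
  reproduces the *procedures* and validates them on synthetic ground truth
  at matched effect magnitudes, not those dataset-specific numbers.
* NormFinder-style stability is a faithful re-implementation of the model
  idea, not of the original applet's exact estimator; rankings can differ
  in close calls.
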
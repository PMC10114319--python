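# Methods

This note records the models implemented in `pericfdna`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that affect results at the margins.

## Positivity scoring and cutoff selection

MaxAF is the maximum mutant allele fraction among a sample's filtered SNV
and Indel calls, in percent; fusion, copy-number and large-rearrangement
calls are excluded because their "allele fraction" is not commensurate with
point-mutation AF. A sample with no eligible call scores 0. Positivity is
strict: a sample is positive iff MaxAF > cutoff; a score exactly at the
cutoff is negative. The convention matters only for ties and is
configurable.

The empirical ROC places one operating point at every distinct observed
score, with sensitivity and specificity computed under the same strict rule,
so the fitted cutoff is always an observed score. AUC is the trapezoidal
area over the curve, which equals the tie-corrected probability that a
random PM sample outscores a random non-PM sample (asserted as a property
test against an O(n²) pairwise oracle). The cutoff maximizes Youden's
J = sensitivity + specificity − 1; ties are broken toward higher
specificity, then higher threshold, reflecting the rule-in framing of a
test that triages patients toward surgical exploration. When the pipeline
fits the cutoff, it uses the training cohort only and applies the value
unchanged to validation; permuting or replacing the validation cohort
cannot move it.

## Filter cascade

Order: depth → supporting reads → population frequency → matched-normal
subtraction. The four rules commute as set filters, so the order only
affects which rule gets credited with a removal in the `FilterReport`
(whose counts must always reconcile: input = output + removals). Boundaries
follow the stated rules exactly: depth < 100 removed (100 kept); SNVs need
≥ 8 supporting reads; indels ≥ 2 in fluid and ≥ 5 in tissue (the two indel
minima are mapped fluid-first and are configurable, since the stated rule
orders them by sample type); population frequency strictly above 0.1%
removed (exactly 0.1% kept); an unknown population frequency is stored as 0
and therefore kept — only variants known to be common are treated as SNPs.
Matched-normal matching is exact on (chrom, pos, ref, alt); no fuzzy indel
matching. TMB divides the SNV/Indel count by the 1.64 Mb panel footprint.

## Copy-number calling

Each coverage profile is normalized to its mean region depth (making
profiles scale-free; any positive rescaling of raw depths leaves calls
unchanged), then GC-corrected by binned medians: regions are split into 10
equal-width bins over the observed GC range and each region is scaled by
global median / bin median, a no-op for GC-flat profiles. The reference is
the per-region mean of ≥ 50 CNV-free profiles prepared the same way; static
probe-design effects cancel in the sample/reference ratio. Copy number is
2 × (sample / reference) on a diploid baseline, with inclusive detection
limits: ≤ 1.75 called deletion, ≥ 2.75 amplification. Regions with zero
reference depth are uncallable and excluded rather than called. A sample is
MSS-A when at least half of its chr20q capture regions are amplified
(inclusive at exactly half), else MSS-N; the threshold is a parameter
because the arm-level rule is a design choice.

The limits are applied per capture region; a gene- or arm-level consumer
should aggregate calls (as `classify_chr20q` does) rather than average
depths first.

## Concordance

Matched lavage/tissue variant sets are partitioned by exact gene-qualified
identity (gene, chrom, pos, ref, alt). Pooled over patients, the three
partition percentages are reported with largest-remainder rounding so they
sum to exactly 100.0. Lavage variant-level sensitivity treats tissue as
truth: 100 × shared / (shared + TIS-only); the same definition applied to
all variants, driver variants, and the SNV/Indel subset reproduces the
study's three sensitivity figures. Cohen's kappa is computed unweighted on
patient × driver-gene binary mutation status per compartment — the unit of
agreement is a design choice (the statistic's input is not dictated by the
data model) and is symmetric and bounded in [−1, 1] by construction.

## Outcomes

Recurrence-free survival runs from surgery to recurrence (event) or last
follow-up (censored); days are converted to months at 30.44 days/month. The
Kaplan–Meier estimator and the log-rank test are implemented from the
standard formulas (product-limit; hypergeometric observed-minus-expected
with 1 df) and are checked against lifelines in the test suite. Lead-time
summaries report both the median (lower-middle convention for even n) and
the mean: for the study's per-case lead times {409, 184, 25} the standard
median is 184 days while the reported "median" of 206 days equals their
arithmetic mean — both are exposed so the reader can see the distinction.
Similarly, the reported mean MaxAF of 18.7% for the three recurrent
positive cases is the truncation of the exact mean of the printed values
(18.766…); the package reports the computed mean. Pathway
over-representation is the upper-tail hypergeometric test with
Benjamini–Hochberg q-values (step-up, monotone in p-order).

Fisher's exact test is the fixed-margin, probability-ordering two-sided
variant, computed by exact integer enumeration of hypergeometric masses so
that tied tables are included without floating-point slack. On the
validation table (5/6 vs 0/5) this yields p = 7/462 ≈ 0.0152; the study
reports 0.031 for that comparison, consistent with a one-sided doubling or
mid-p variant it does not name. The package reports the standard variant
rather than tuning to match.

## Synthetic cohorts: what they emulate

The generator reproduces, per patient and from one seed (every patient has
an independent RNG stream keyed by seed, arm and index, so subsets are
reproducible regardless of cohort size):

- **Tissue mutations.** Driver genes are Bernoulli per arm at the reported
  tissue frequencies (PM: KRAS 0.529, BRAF 0.235, TP53 0.765, APC 0.471,
  PIK3CA 0.176, SMAD4 0.235; non-PM analogues including BRAF 0). Passenger
  mutations are Poisson with means 3.5 (PM) and 8.35 (non-PM), chosen so
  expected tissue TMB over 1.64 Mb matches the reported arm means (3.93 and
  6.55 mut/Mb). A small Poisson(0.3) count of structural rows
  (fusion/CNV/LGR) joins the somatic plan; they pass filters and share like
  other variants but never define MaxAF.
- **Lavage sharing.** Tissue variants enter the lavage with probability
  0.92 for drivers (the reported driver-level lavage sensitivity) and 0.60
  for passengers, plus lavage-private variants (driver top-ups to the
  reported lavage frequencies, and Poisson(1.55) private passengers). These
  rates were solved analytically so the pooled partition approximates the
  reported 56.0 / 20.3 / 23.7 shared/TIS-only/FLD-only split.
- **MaxAF.** Each positive lavage draws a target MaxAF from a Beta
  distribution (PM mean 40%, concentration 10; non-PM false positives mean
  18.7%), pins one clonal SNV/Indel at the target and scales the rest below
  it; observed AFs are binomial draws at the sampled depth (~35,000× lavage,
  ~1,000× tissue, 10% CV), so supporting_reads ≤ depth holds by
  construction. Non-PM patients are cfDNA positive with probability 5/23;
  30% of the negatives carry a sub-cutoff trace, the rest score 0.
- **Germline.** Poisson(30) common SNPs per patient (AF ≈ 0.5, population
  frequency 0.2–50%) contaminate all three compartments, plus Poisson(2)
  rare germline variants with population frequency 0 that only
  matched-normal subtraction can remove — this separates the two germline
  defenses in tests.
- **Chemotherapy false negatives.** A chemotherapy-pretreated PM patient's
  lavage is suppressed to MaxAF 0 with a configurable probability (the
  validation cohort default plants one such patient in six, reproducing the
  study's single false negative).
- **Coverage.** A synthetic 240-region capture panel (~10% on chr20q) with
  fixed per-region probe effects and a linear GC bias, per-sample library
  scale, and gamma depth noise with CV 1.5%. The noise level is a free
  design parameter set once so the caller's required operating
  characteristics at the 1.75/2.75 limits hold at defaults (≥ 95%
  sensitivity for copy number 3, < 1% region-level false calls); at 2.5% CV
  the 12.5% ratio margin is only ~1.4σ. MSS-A tumors get a 1.5× chr20q
  gain (rate 4/22 in non-PM, 0 in PM).
- **Outcomes.** Exponential recurrence hazards with ratio 7.1 between
  cfDNA-positive and negative patients (baseline 0.0084/month, set so
  ~11% of negatives recur within the follow-up window), administrative
  censoring uniform over 9–18.6 months (median ≈ 13.8).

What it does **not** emulate: read-level artifacts (UMI consensus errors,
strand bias, mapping error — depth and supporting reads are summary draws),
subclonal phylogenies and AF correlation structure between compartments,
panel-specific mutability per gene, fuzzy indel representation differences
between compartments, imaging dates (so lead times come only from the
study's printed per-case values), and competing-risk or non-proportional
hazards. Passing tests therefore demonstrate that the analysis code is
correct and well-calibrated under the study's summary statistics — not that
the assay itself performs as reported on real specimens.

## Problem sizes and tolerances

Property suites run at n ≤ 200 with fixed seeds; parameter-recovery tests
use 500 patients per arm and 3-standard-error bands; the Fisher
implementation is checked exhaustively against enumeration on all 2×2
tables with total ≤ 40 and against an independent library implementation on
sampled tables. Reported percentages are rounded half-up to one decimal
(78.26 → 78.3); undefined metrics (zero denominators, constant raters, no
events) raise typed errors or are reported as null, never coerced to 0.
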
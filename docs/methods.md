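# Methods

## Setting and assumptions

The package implements summary-data two-sample Mendelian randomization for
a drug-target (cis) design: one or two variants in the target gene region
proxy pharmacological modulation of the target, the exposure is a
standardized circulating biomarker, and outcomes are binary disease traits
or quantitative downstream biomarkers. The usual instrumental-variable
assumptions apply — relevance (enforced empirically via the significance
filter and the F statistic), independence from confounders, and exclusion
restriction (no path to the outcome except through the exposure). Effects
are assumed linear on the exposure scale and log-odds scale, with no
interaction. Exposure and outcome cohorts must not share individuals; the
two-sample structure is what lets first-order ratio SEs be valid.

## Instrument selection

Candidates are filtered on the reported association p-value (default
threshold 5e-8, applied to the reported p rather than recomputed from
beta/SE, preserving fidelity to source tables), a minor-allele-frequency
floor (strict `min(eaf, 1-eaf) > 0.01`), and removal of palindromic (A/T,
C/G) variants whose strand cannot be resolved from alleles alone.
Survivors are greedily LD-pruned: sort by ascending p-value (ties broken
lexicographically by rsid so results are input-order invariant), keep the
best, drop any later candidate with r² at or above the threshold (default
0.3) against a kept variant. The greedy rule is the standard clumping
heuristic; the thresholds are exposed in `SelectionCriteria`.

## Harmonization and alignment

The outcome record is oriented onto the exposure's effect allele by exact
allele match, allele swap (negate beta, complement EAF), strand flip
(complement bases), or both. Palindromic pairs are refused under the
default `drop` policy; the `infer_by_eaf` policy orients by whether both
EAFs fall on the same side of 0.5 and refuses when either is within 0.08
of 0.5 (the conventional ambiguity band). A final alignment step orients
every pair to the exposure-increasing allele, which fixes the reporting
sign convention; the Wald ratio is invariant under all of these
operations, and the property suite asserts it.

## Estimation

Wald ratios default to the first-order SE (`se_Y/|beta_X|`), the
convention of standard two-sample MR software; the second-order
delta-method SE is available for sensitivity and always dominates the
first-order value. IVW uses fixed-effect weights `beta_X^2/se_Y^2` with no
multiplicative residual scaling — with two instruments residual scaling is
degenerate — and treats instruments as uncorrelated even when the bundled
r² between them is 0.11, mirroring the published analysis. Consequences of
that approximation are discussed under limitations. Confidence intervals
are normal-theory (`z = 1.96` at 95%); p-values are two-sided normal,
equivalent to the chi-square(1) tail of the squared z-score. Odds-scale
fields are populated only for binary outcomes, by exponentiation at
reporting time; all pooling happens on the log scale.

## Meta-analysis

Cohorts (not SNPs) are the meta-analytic unit: each outcome GWAS
contributes one estimate (Wald with one instrument, IVW with more), and
cohorts of the same outcome trait are pooled. Fixed effects uses
inverse-variance weights; heterogeneity is Cochran's Q with df = k−1,
I² = max(0, (Q−df)/Q)·100 (floored at zero by definition), and the
random-effects model is DerSimonian–Laird with
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). k = 1 returns a degenerate but
well-formed result (Q = 0, Q p-value 1) so the pipeline's reporting is
uniform. The automatic model rule selects fixed effects unless the Q test
rejects at α = 0.05. Published per-cohort results available only as
OR (CI) are reconstructed on the log scale with
SE = ln(CI_high/CI_low)/(2·1.96); reconstruction at two-decimal reporting
precision reproduces the published pooled NAFLD OR exactly at that
precision, which bounds the error this introduces.

## Instrument strength and power

F = (beta/SE)² per variant. Instrument R² on a unit-variance exposure is
2p(1−p)beta² per variant, summed across independent variants. Binary-
outcome power follows the non-centrality-parameter formulation for
summary-data MR: the case fraction K attenuates the observable log-odds
effect to b = K(OR/(1+K(OR−1)) − 1) with variance
v = (K(1−K) − b²)/(N·R²), and power is the noncentral-χ²(1, b²/v) upper
tail beyond the central critical value at α (default 0.05, two-sided).
Power defaults to the single primary instrument's R²; the two-instrument
sum is available. At the bundled inputs this reproduces the published 98%
for the larger NAFLD cohort. The published 84% for the second cohort is
not reproducible from any combination of its printed N, K, OR and R²
values; the discrepancy is documented here rather than asserted anywhere.

## Synthetic data generator

`targetmr.simulate` emulates the study design end to end with known
truth. Genotypes: two latent haplotypes per person from a multivariate
normal, dichotomized at the allele-frequency quantile and summed, giving
Hardy–Weinberg genotypes with configurable EAFs. Because dichotomization
attenuates correlation, the latent correlation for each variant pair is
solved numerically (bivariate-normal orthant probability, Brent's method)
so the realized Pearson dosage correlation matches the configured
`pairwise_r`; the solve is cached across replicates. Exposure: centred
additive genetic score plus Gaussian noise with variance 1 − var(G), so
the exposure has unit variance by construction (the generator refuses
effect sizes implying var(G) ≥ 1). Outcome: Bernoulli with logit
`intercept + gamma·exposure (+ direct effects·dosage)`, drawn in an
independent genotype cohort — the two-sample property holds by
construction. Summary scans are per-variant simple linear regression
(exposure) and per-variant logistic regression (outcome), yielding records
in the same format as real summary statistics, plus the sample LD matrix.
All randomness descends from one seed through a spawned seed sequence;
identical configs are bit-identical.

Default architecture for the bundled scenarios: two variants with effects
0.17 and 0.09 SD per allele at EAFs 0.38 and 0.82 (the published exposure
associations), outcome intercept −2.5 (prevalence ≈ 7.6%, matching the
larger NAFLD cohort's case fraction), causal log-odds gamma = 0.6 per SD
(≈ the published cohort OR of 1.99 ≈ e^0.69, rounded to a plausible
working value), cohorts of 50,000. The CLI `simulate` default sets
`pairwise_r = 0.33` (r² ≈ 0.11, the published LD between the two
instruments).

What the generator does *not* emulate: genome-wide variant panels,
population structure and relatedness, winner's curse in instrument
discovery, covariate adjustment, and liability-scale outcome models.
Passing recovery tests therefore show the estimators are calibrated under
the stated generative model, not that real-data biases (pleiotropy,
selection, stratification) are absent.

## Calibration checks and their design

The recovery suite runs the generator and full estimation path over
replicates: (i) with gamma = 0.6 and two *independent* instruments at the
published effect sizes, the IVW 95% CI must cover the truth in ≥ 90 of 100
replicates; (ii) with gamma = 0, the single-instrument Wald test at
α = 0.05 must reject in 2–9% of 500 replicates. The coverage experiment
deliberately uses independent instruments because the IVW estimator
assumes them; under correlated instruments (the `pairwise_r = 0.33`
setting) the correlation-ignoring SE is understated and coverage drops a
few points below nominal — that behaviour is a property of the standard
estimator, retained intentionally, not a defect the generator should mask.

## Numerical choices and degenerate inputs

- Wald ratio with zero exposure beta raises rather than returning
  infinity; zero outcome beta returns a clean null (OR = 1, p = 1).
- Exponentiation to the odds scale saturates to `inf` beyond the double-
  precision range instead of overflowing.
- Logistic-scan p-values are clamped away from exact zero to respect the
  record invariant `p ∈ (0, 1]`.
- Monomorphic simulated variants are skipped with a log entry rather than
  producing undefined regressions.
- The results table renders odds-scale columns at two decimals (the
  reporting convention of the field) and log-scale columns at six
  significant digits; round-tripping preserves values at rendered
  precision.

## Known limitations

- Correlation-aware IVW (generalized least squares on the LD matrix) is
  not implemented; with the bundled r² = 0.11 the pooled SE is modestly
  optimistic, as discussed above.
- Pleiotropy-robust estimators (MR-Egger, weighted median/mode) are out of
  scope; with one or two cis instruments they are not identifiable anyway.
- Published inputs are rounded (betas to two decimals, SEs to three), so
  quantities derived from them carry a few percent of input-rounding
  error; one published biomarker ratio (CRP scaled by the secondary
  instrument, printed −0.62 vs −0.667 recomputed from rounded inputs)
  cannot be reconciled within that bound and is documented rather than
  asserted.
- Indels, multi-allelic variants, genome coordinates and proxy-variant
  lookup are out of scope; the analysis is rsID-keyed.
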
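# targetmr

Target-based two-sample Mendelian randomization (MR) from GWAS summary
statistics: instrument selection and harmonization, Wald-ratio and
inverse-variance-weighted (IVW) causal estimation, cross-cohort
meta-analysis with heterogeneity statistics, instrument-strength and
binary-outcome power calculations, and a synthetic summary-statistics
generator with known ground truth for end-to-end validation.

## The scientific problem

Drug-target (cis) MR asks whether pharmacologically modulating a protein
would change disease risk, using germline variants in the target's gene
region as natural proxies for the drug. The motivating application shipped
with the package is IL-6 receptor blockade: the missense variant rs2228145
(IL-6R Asp358Ala) increases IL-6R proteolysis and dampens classical IL-6
signaling much like tocilizumab, which shows up as a *higher* circulating
IL-6 level. Scaling outcome associations by the IL-6 association therefore
estimates the effect of inhibiting the IL-6 pathway. The bundled tables
(`targetmr.datasets`) carry the published per-variant associations of
rs2228145 and rs12048091 with standardized IL-6 level, the downstream
biomarkers CRP and fibrinogen, the positive controls rheumatoid arthritis
and coronary heart disease, and the per-cohort NAFLD odds ratios from two
independent case-control GWASs.

## Methods at the core

For instrument *j* with exposure association β̂_Xj (SE σ_Xj) and outcome
association β̂_Yj (SE σ_Yj) on a shared, exposure-increasing effect allele:

- **Wald ratio**: β̂_j = β̂_Yj / β̂_Xj, with first-order SE σ_Yj/|β̂_Xj|
  or the second-order delta-method form
  √(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴).
- **IVW** over independent instruments: weights w_j = β̂_Xj²/σ_Yj²,
  β̂ = Σw_jβ̂_j / Σw_j, SE = 1/√(Σw_j) — identical to fixed-effects
  pooling of the per-instrument Wald estimates.
- **Meta-analysis** across cohorts: inverse-variance fixed effects with
  Cochran's Q, I² = max(0, (Q−df)/Q)·100, and DerSimonian–Laird τ² for the
  random-effects model; the automatic rule keeps fixed effects unless the
  Q test rejects homogeneity at α = 0.05.
- **Instrument strength**: F = (β̂_X/σ_X)², the squared z-score.
- **Power** (binary outcome, case fraction K, causal odds ratio OR per SD
  exposure, instrument R² = Σ 2p_j(1−p_j)β̂_Xj²):
  b = K(OR/(1+K(OR−1)) − 1), v = (K(1−K) − b²)/(N·R²), and power is the
  noncentral-χ²(1, b²/v) tail beyond the central χ²(1) critical value.

## Worked example

```python
from targetmr import datasets, wald_ratio, harmonize_pair, align_to_increasing
from targetmr import (pool_fixed, estimate_from_or_ci, instrument_r2,
                      binary_mr_power, PowerScenario, f_statistic)

il6 = {r.rsid: r for r in datasets.il6_exposure_associations()}
chd = {r.rsid: r for r in datasets.outcome_associations("coronary_heart_disease")}

pair = align_to_increasing(harmonize_pair(il6["rs2228145"], chd["rs2228145"]))
res = wald_ratio(pair)
print(f"CHD per SD IL-6: OR {res.odds_ratio:.2f} "
      f"(95% CI {res.or_ci_low:.2f}-{res.or_ci_high:.2f}), p = {res.pvalue:.2g}")
print(f"F statistic (rs2228145): {f_statistic(il6['rs2228145']):.1f}")

cohorts = [estimate_from_or_ci(*ci, outcome=name)
           for name, ci in datasets.nafld_cohort_ors().items()]
pooled = pool_fixed(cohorts)
print(f"NAFLD meta-analysis: OR {pooled.odds_ratio:.2f} "
      f"({pooled.or_ci_low:.2f}-{pooled.or_ci_high:.2f}), "
      f"Q = {pooled.q:.2f}, I2 = {pooled.i2:.0f}%, p = {pooled.pvalue:.3f}")

r2 = instrument_r2(0.38, 0.17)
power = binary_mr_power(PowerScenario(n=19264, case_fraction=1483/19264,
                                      or_per_sd=1.99, r2=r2))
print(f"Instrument R2 = {r2:.4f}; power at OR 1.99 = {power:.0%}")
```

Output:

```
CHD per SD IL-6: OR 0.75 (95% CI 0.66-0.84), p = 5.7e-07
F statistic (rs2228145): 200.7
NAFLD meta-analysis: OR 1.80 (1.26-2.57), Q = 0.53, I2 = 0%, p = 0.001
Instrument R2 = 0.0136; power at OR 1.99 = 98%
```

Reading the numbers: each SD of genetically higher IL-6 (i.e. stronger
IL-6 pathway inhibition) lowers coronary-heart-disease odds by 25% — the
expected direction for a positive control, confirming the instrument
behaves like IL-6R blockade. The F statistic of ~200 rules out weak-
instrument bias. Pooling the two NAFLD cohorts gives OR 1.80 per SD with
no detectable heterogeneity (I² = 0), and the larger cohort had 98% power
to detect its observed effect.

## Command line

```bash
targetmr run --config analysis.yaml          # full pipeline
targetmr select --exposure exp.tsv --ld ld.tsv --out instruments.tsv
targetmr estimate --exposure exp.tsv --outcome out.tsv --out est.tsv
targetmr meta --estimates cohorts.tsv --out meta.tsv
targetmr power --n 19264 --case-fraction 0.077 --or-per-sd 1.99 --r2 0.0136
targetmr simulate --out-dir sim/ --seed 1 --gamma 0.6
```

`run` executes select → harmonize → align → per-cohort estimate →
meta-analysis → F table → power table from a single YAML config and writes
one TSV per stage plus a combined table; composing the subcommands
reproduces it file-for-file.

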
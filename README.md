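# rcsample

Sampling designs for internal validation samples in exposure
measurement-error correction — a simulation engine, estimator library and
command-line tool for studying how the *choice of validation subsample*
(random, stratified random, or extremes of the error-prone measure)
affects the bias and efficiency of regression-calibration-corrected
exposure-outcome estimates.

## The problem

Large epidemiologic studies often replace an expensive gold-standard
exposure measurement with a cheap error-prone substitute: the motivating
setting is visceral adipose tissue (VAT, quantified by MRI) replaced by
waist circumference (WC, a tape measure) in a study of insulin resistance
(IR).  Regressing the outcome on the substitute attenuates the exposure
coefficient.  If a subset of the cohort — the *internal validation sample*
(IVS) — receives both measurements, the measurement-error model can be
estimated and the association corrected.  Two design questions follow:

1. **Who should be in the validation sample?**  Random selection, a
   stratified random sample over strata of the substitute, or the extremes
   of the substitute (which maximize leverage for estimating a linear
   calibration model)?
2. **How should the correction use it?**  With `Y` the outcome, `X` the
   gold standard, `W` the substitute and `Z` confounders:
   - *IVS-restricted*: OLS of `Y ~ X + Z` in the validation sample only;
   - *standard regression calibration*: replace `W` for everyone by
     `E[X | W, Z]` estimated in the validation sample, then fit
     `Y ~ X̂ + Z`;
   - *validation regression calibration*: use observed `X` inside the
     validation sample and `X̂` outside it;
   - *efficient regression calibration*: the inverse-variance-weighted
     mean of the IVS-restricted and standard-RC estimates.

The package generates synthetic cohorts from a fully specified mechanism
(known true coefficient β = 0.2 of IR on VAT), applies every combination
of sampling strategy and analysis over a factorial grid of measurement-
error strength (R² of WC given VAT), residual skewness of VAT, and
linear/nonlinear calibration shape, and summarizes percentage bias, MSE,
CI coverage and Monte Carlo standard errors.  A differential-error variant
(WC and IR share a latent Bernoulli variable) demonstrates when
calibration fails and when nonrandom sampling adds collider
stratification bias.  See `docs/methods.md` for the full mechanism and
estimator details.

## Worked example

Run one scenario (R² = 0.6, skewness 1.5, linear, 40% validation sample,
200 replications of n = 650):

```bash
rcsample demo --reps 200 --seed 1
```

which prints the 13 analysis-by-strategy summaries:

```
        method   strategy  pct_bias    mse  coverage  emp_se  model_se  mcse_bias
   uncorrected       None  -53.1628 0.0119    0.0150  0.0247    0.0239     0.0017
ivs_restricted     random    2.5239 0.0029    0.9350  0.0534    0.0491     0.0038
   standard_rc     random    1.0719 0.0030    0.9400  0.0549    0.0538     0.0039
 validation_rc     random    1.9244 0.0020    0.9400  0.0441    0.0400     0.0031
  efficient_rc     random    1.4264 0.0021    0.9050  0.0457    0.0361     0.0032
ivs_restricted stratified   -2.6130 0.0020    0.9300  0.0443    0.0426     0.0031
   standard_rc stratified   -6.4976 0.0027    0.9400  0.0500    0.0480     0.0035
 validation_rc stratified   -5.2552 0.0016    0.9200  0.0389    0.0363     0.0028
  efficient_rc stratified   -4.4769 0.0018    0.8550  0.0410    0.0318     0.0029
ivs_restricted   extremes    0.2898 0.0016    0.9500  0.0406    0.0415     0.0029
   standard_rc   extremes   -7.0626 0.0025    0.9350  0.0485    0.0475     0.0034
 validation_rc   extremes   -4.1870 0.0015    0.9350  0.0376    0.0362     0.0027
  efficient_rc   extremes   -2.9810 0.0016    0.8750  0.0390    0.0312     0.0028
```

Read it as: ignoring measurement error attenuates the association by ~53%;
every corrected analysis is near-unbiased here, but stratified and
extremes sampling buy a smaller MSE for validation regression calibration
(0.0015–0.0016 vs 0.0020 under random sampling) at the price of a few
percent downward bias — the full-scale version of this trade-off is the
package's main result.  `mcse_bias` is the Monte Carlo standard error of
the bias at 200 replications; at this size the per-cell percentage bias
is only pinned down to ±1.5 points or so, which is why the corrected
analyses scatter around zero.

The same machinery is scriptable:

```python
from rcsample import ScenarioConfig, run_scenario, mse_reduction

table = run_scenario(ScenarioConfig(r2_target=0.6, skewness=1.5,
                                    val_fraction=0.40, n_reps=500, seed=1))
print(mse_reduction(table, "stratified", "validation_rc"))
```

and the five estimators are scikit-learn compatible (`fit(X, y)` on a
DataFrame whose `vat` column is NaN outside the validation sample,
fitted attributes `coef_`, `se_`, `ci_`).

Full reproduction grids ship with the package:

```bash
rcsample simulate --config study_main --out-dir results/main
rcsample reduce --results results/main/results.csv
```

(`study_main`, `study_frac10`, `study_frac25`, `study_frac50`,
`study_differential`; 40 scenarios × 5,000 replications each for the main
grid — hours of CPU; use `--reps`/`--subset` to scale down.)

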
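# Methods

This note documents the data-generating mechanism, the estimators, the
Monte Carlo protocol and the numerical and design choices behind them.
Everything here is computed by the package's tests or by
`scripts/acceptance.py`; no number is quoted from elsewhere.

## Data-generating mechanism

Each synthetic cohort of size n (default 650) mimics a cross-sectional
obesity study.  With the second parameter of every normal distribution a
**variance**:

    sex ~ Bernoulli(0.5)
    age ~ Uniform(45, 65)                                   [years]
    TBF | sex, age ~ N(-2 + sex + 0.01 age, 0.5)            [standardized]
    VAT = 0.4 - 2 sex + 0.01 age + 0.9 TBF + (eps - E eps)
          eps ~ Gamma(shape 6λ, scale sqrt(0.5/(6λ)))
    WC  | VAT ~ N(0.8 · m(VAT), τ²)
    IR  | VAT, sex, age, TBF ~ N(0.5 + β VAT - 0.5 sex
                                 + 0.01 age + 0.3 TBF, 0.3)

with β = 0.2 the estimand (the conditional effect of the gold-standard
exposure VAT on the outcome IR), m(v) = v in the linear variant and the
sign-preserving square root m(v) = sign(v)·sqrt(|v|) in the nonlinear
variant (VAT is negative for roughly a third of individuals on this
standardized scale, so a plain square root is undefined; the
sign-preserving transform is the natural odd extension).

The gamma parameterization is the one under which the subtracted constant
6λ·sqrt(0.5/(6λ)) equals the gamma mean, so eps is centered; its variance
is shape·scale² = 0.5 for *every* λ while its skewness is 2/sqrt(6λ).
Residual skewness is therefore a free design factor that never moves the
marginal mean or variance of VAT; the variance reading of N(·,·) is
corroborated independently: it implies Var(VAT) = 1.1²·0.25 +
0.019²·(20²/12) + 0.81·0.5 + 0.5 ≈ 1.2195 and hence τ = 0.4417 at
R² = 0.8, reproducing the differential scenario's stated τ = 0.44.

**Design factors.**  R² of the simple regression of WC on VAT
∈ {0.2, 0.4, 0.6, 0.8, 0.9}; skewness ∈ {0.1, 1, 1.5, 3} (λ = 2/(3s²));
linear/nonlinear — a 5×4×2 = 40-scenario full factorial.  The validation
fraction (0.10/0.25/0.40/0.50) and the differential-error flag extend the
grid.

**Solving τ from R².**  τ (the residual SD of WC given VAT) is obtained
by monotone root-finding: one large calibration cohort (default 10⁶
individuals) is drawn, and because WC(τ) = m + τ·w with fixed draws, the
sample R²(τ) is an explicit rational function of τ computed from five
base moments; Brent's method then solves R²(τ) = target to near machine
precision at negligible cost.  The analytic closed form
τ² = θ²·Var(VAT)·(1−R²)/R² for the linear model is the independent
cross-check in the tests.

τ is always calibrated **under the linear mechanism** and shared with the
nonlinear variant of the same (R², skewness) cell.  This is forced, not
merely convenient: under the nonlinear mean function the simple-regression
R² of WC on VAT is bounded above by the squared correlation of m(VAT)
with VAT (≈ 0.894 at skewness 0.1, lower at higher skewness), so the
design's R² = 0.9 level could not exist if τ were calibrated under the
nonlinear model.  The R² levels therefore index the measurement-error
variance; the nonlinear variant's *realized* R² sits slightly below
nominal, which is why the uncorrected analysis is slightly more biased
there.

**Differential error.**  WC | VAT ~ N(0.8·VAT + τ·U, τ²) and IR gains a
term sqrt(0.3)·U, with U ~ Bernoulli(0.5) latent and τ = 0.44 fixed.
The substitute's error then depends on the outcome through U
(differential measurement error), and selecting the validation sample on
WC — a collider between VAT and U — biases even the gold-standard
analysis within the selected sample.  The calibration slope θ in this
variant is not separately specified anywhere; it is kept at the main
mechanism's 0.8, a choice corroborated by the uncorrected analysis: the
implied large-sample bias (0.8·0.2·0.5 + 0.44·sqrt(0.3)·0.25)/(0.8²·0.5 +
0.44²·0.25 + 0.44²) / 0.2 − 1 ≈ +25% matches the simulation.

## Sampling strategies

With m = round(fraction · n) (round-half-to-even, minimum 1):

- **random** — simple random sample without replacement;
- **extremes** — the floor(m/2) lowest and ceil(m/2) highest WC values,
  ties broken stably by row order;
- **stratified** — k = 10 equal-width strata spanning [min WC, max WC]
  (half-open intervals, last closed), base quota an integer split of m
  (remainder to the lowest-indexed strata), undersized strata fully
  included, and the resulting deficit redistributed one unit at a time
  round-robin over strata in order of decreasing remaining capacity until
  exactly m rows are selected; simple random sampling within strata.

The redistribution order is a determinism choice: any order that spreads
the shortage "equally" yields the same counts up to ties, and the results
are insensitive to it.  Masking the gold standard outside the selection is
an explicit operation (NaN in the `vat` column), so the missingness
pattern itself encodes the validation sample for the estimators.

## Estimators

All five analyses adjust for the mechanism's confounders (sex, age, TBF)
and report a Wald 95% CI with critical value 1.96.  OLS uses the
classical model-based covariance σ̂²(XᵀX)⁻¹ with the unbiased residual
variance.  Replications with rank-deficient designs are flagged
non-converged, dropped from summaries, and counted (`n_failed`; it is
zero throughout the shipped grids).

The two-step calibration estimators (standard and validation RC) estimate
the calibration model X ~ W + Z in the validation sample, form
predictions, and fit the outcome model with the predicted (or hybrid)
exposure.  Their standard error propagates the calibration-stage
uncertainty via a stacked estimating-equations sandwich over the joint
(calibration, outcome) parameter vector — the multivariate delta method.
The hybrid exposure of validation RC enters the Jacobian with weight
1 − v_i per row (observed gold-standard values do not move with the
calibration fit); standard RC uses weight 1.  A nonparametric bootstrap
(500 resamples of the full two-step procedure) agrees with the sandwich
SE within 10% in the tests, and the mean model-based SE tracks the
empirical SD of the estimates within 10% across nondifferential
scenarios.

Efficient RC pools the IVS-restricted and standard-RC estimates with
simple inverse-variance weights, deliberately ignoring their positive
correlation (both use the same validation sample).  Its model SE
therefore understates the empirical SD by roughly 10–15% and its CIs
undercover mildly (≈ 0.89–0.92 observed); the test suite asserts this
behavior rather than hiding it.

## Monte Carlo protocol

Each replication generates one cohort and produces 13 estimate records:
the uncorrected analysis plus {IVS-restricted, standard RC, validation
RC, efficient RC} × {random, stratified, extremes}.  Per
(method, strategy) cell the engine reports bias, percentage bias
(100·bias/β), MSE, coverage, empirical SD, sqrt of mean squared model SE,
and Monte Carlo standard errors: MCSE(bias) = emp_se/√K,
MCSE(mse) = SD((β̂−β)²)/√K, MCSE(coverage) = sqrt(c(1−c)/K).  The
decomposition mse = bias² + emp_se²·(K−1)/K holds to 10⁻¹² by
construction and is asserted.

**Seeding.**  A master seed spawns one `numpy` SeedSequence per
(scenario-parameters, validation fraction, replication), so any single
replication can be regenerated in isolation, results are bit-identical
across runs, and grids parallelize (joblib) with results independent of
worker count.  τ-calibration streams are keyed on (master seed, R²,
skewness) so grids at different fractions share identical τ.

**Efficiency comparisons.**  The MSE decrease of a strategy vs random
sampling is 100·(1 − MSE_strategy/MSE_random) per scenario, averaged
unweighted over scenarios.  Averages can be taken over the full
40-scenario grid or over the non-redundant design subset that drops
R² = 0.9 (behaves like 0.8) and skewness = 1 (behaves like 1.5) — two
robustness levels whose results duplicate their neighbors;
`nonredundant_subset` exposes it and the headline averages in the
acceptance script use it.  The two averages differ by about two points
for validation RC at the 40% fraction (the redundant levels have
below-average gains), and by much less for the IVS-restricted analysis.

A convergence caveat discovered while validating the engine: at the 10%
validation fraction (m = 65) under *random* sampling, the calibration
slope is a noisy denominator and the validation-RC estimator is
heavy-tailed — in one scenario the top 1% of replications carry ~18% of
the MSE.  The plug-in reduction estimator 1 − MSE_s/MSE_r is then biased
downward at small K (Jensen's inequality applied to the noisy
denominator), so 10%-fraction efficiency comparisons use more
replications than the 40%-fraction ones.  Problem sizes: acceptance
script — 1,500 replications/scenario at the 40% fraction, 4,000 at 10%,
5,000 for the differential scenario; test suite — 500, 2,000 and 2,000
respectively.

## What the generator does and does not emulate

The generator reproduces the stated mechanism exactly: confounding by
sex/age/TBF, controlled R² and residual skewness, nondifferential or
differential error, a known conditional effect.  It does **not** emulate
real anthropometric scales (WC in cm, VAT in cm²), missing data,
nonlinearity of the outcome model, heteroskedastic measurement error, or
the covariate set of a real cohort (ethnicity, smoking, ...).  Passing
tests therefore demonstrate correctness of the estimators and the
engine's Monte Carlo arithmetic under this mechanism — not that any
particular real study's correction is unbiased.

## Known limitations

- The efficient-RC interval undercovers by construction (see above);
  a pooled estimator using the joint covariance of its components would
  fix this but is out of scope.
- The differential-error scenario's collider bias for *extremes* sampling
  in the IVS-restricted analysis has a large-sample value of ≈ +13%
  under the stated equations — checked by direct computation on cohorts
  of 2×10⁶ and insensitive to a wide range of alternative mechanism
  readings (calibration slope, skewness, tail fraction, residualized
  selection).  The package reports what the mechanism implies for this
  cell; it is the one quantity in the differential experiment whose
  magnitude is sensitive to exactly how tail selection interacts with
  the latent variable.
- Stratified sampling uses fixed k = 10 equal-width strata; quantile
  strata would behave differently for heavily skewed substitutes.
- Failed fits are dropped, not imputed; at these designs they are
  nonexistent (rank deficiency would require degenerate cohorts).
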
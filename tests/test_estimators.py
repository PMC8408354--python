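"""The five analyses: OLS plumbing, calibration correctness in limiting
cases, sandwich variance against a bootstrap, and pooling arithmetic."""

import numpy as np
import pandas as pd
import pytest

from rcsample.dgm import DGMParams, generate_cohort, lambda_from_skewness
from rcsample.estimators import (
    EfficientRegressionCalibration,
    EstimateRecord,
    RankDeficiencyError,
    StandardRegressionCalibration,
    UncorrectedRegression,
    ValidationRegressionCalibration,
    ValidationSubsetRegression,
    beta_to_percent,
    design_frame,
    est_efficient_rc,
    est_ivs_restricted,
    est_standard_rc,
    est_uncorrected,
    est_validation_rc,
    fit_linear,
    pool_inverse_variance,
)
from rcsample.sampling import mask_nonvalidation, select_random


class TestFitLinear:
    def test_hand_solved_normal_equations(self):
        # y ~ 1 + 2x through 5 points; normal equations by hand:
        # X'X = [[5, 10], [10, 30]], X'y = (25.3, 70.7),
        # (X'X)^{-1} = [[0.6, -0.2], [-0.2, 0.1]] -> b = (1.04, 2.01)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.9, 5.2, 7.0, 9.1])
        X = np.column_stack([np.ones(5), x])
        coef, _cov = fit_linear(y, X)
        np.testing.assert_allclose(coef, [1.04, 2.01], rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        y = X @ np.array([1.0, 0.5, -0.2, 0.0]) + rng.normal(size=60)
        coef, cov = fit_linear(y, X)
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(coef, fit.params, rtol=1e-10)
        np.testing.assert_allclose(cov, fit.cov_params(), rtol=1e-8)

    def test_exact_fit_zero_residual_variance(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ np.array([2.0, -1.0])
        coef, cov = fit_linear(y, X)
        np.testing.assert_allclose(coef, [2.0, -1.0], atol=1e-10)
        np.testing.assert_allclose(cov, 0.0, atol=1e-18)

    def test_row_permutation_invariance(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        perm = rng.permutation(30)
        coef, _ = fit_linear(y, X)
        coef_p, _ = fit_linear(y[perm], X[perm])
        np.testing.assert_allclose(coef, coef_p, rtol=1e-10)

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(RankDeficiencyError):
            fit_linear(rng.normal(size=20), X)

    def test_too_few_rows_raises(self):
        with pytest.raises(RankDeficiencyError):
            fit_linear(np.ones(2), np.ones((2, 2)))


@pytest.fixture(scope="module")
def noiseless():
    cohort = generate_cohort(DGMParams(tau=0.0), n=650, seed=31)
    sel = select_random(650, 260, seed=32)
    gold_design = np.column_stack(
        [np.ones(650), cohort.vat, cohort.sex, cohort.age, cohort.tbf])
    gold_coef, _gold_cov = fit_linear(cohort.ir, gold_design)
    return cohort, sel, gold_coef[1]


class TestZeroNoiseEquivalence:
    """At tau = 0 the substitute is an exact rescaling of the gold standard:
    every analysis must agree with the gold-standard full-cohort OLS."""

    def test_uncorrected_is_exact_exposure_rescaling(self, noiseless):
        cohort, _sel, gold_beta = noiseless
        rec = est_uncorrected(cohort)
        assert rec.beta_hat == pytest.approx(gold_beta / 0.8, rel=1e-9)

    def test_calibration_methods_recover_gold_standard(self, noiseless):
        cohort, sel, gold_beta = noiseless
        for est in (est_standard_rc, est_validation_rc):
            rec = est(cohort, sel)
            assert rec.beta_hat == pytest.approx(gold_beta, rel=1e-7)

    def test_full_selection_equals_gold_standard(self, noiseless):
        cohort, _sel, gold_beta = noiseless
        sel_all = select_random(650, 650, seed=1)
        for est in (est_ivs_restricted, est_validation_rc):
            rec = est(cohort, sel_all)
            assert rec.beta_hat == pytest.approx(gold_beta, rel=1e-9)


class TestConsistencyUnderNondifferentialError:
    def test_rc_estimators_near_truth_at_large_n(self):
        params = DGMParams(tau=0.44, lam=lambda_from_skewness(1.5))
        cohort = generate_cohort(params, n=100_000, seed=41)
        sel = select_random(cohort.n, 40_000, seed=42)
        for est in (est_standard_rc, est_validation_rc):
            rec = est(cohort, sel)
            assert rec.beta_hat == pytest.approx(0.2, abs=0.01)

    def test_uncorrected_attenuated(self, small_cohort):
        _params, cohort = small_cohort
        rec = est_uncorrected(cohort)
        assert rec.beta_hat < 0.2  # attenuation toward zero


class TestSandwichAgainstBootstrap:
    @pytest.mark.parametrize("est_fun, cls", [
        (est_standard_rc, StandardRegressionCalibration),
        (est_validation_rc, ValidationRegressionCalibration),
    ])
    def test_delta_method_se_within_10pct_of_bootstrap(self, est_fun, cls):
        params = DGMParams(tau=0.44, lam=lambda_from_skewness(0.1))
        cohort = generate_cohort(params, n=650, seed=51)
        sel = select_random(650, 260, seed=52)
        rec = est_fun(cohort, sel)

        masked = mask_nonvalidation(cohort, sel)
        X = design_frame(masked)
        rng = np.random.default_rng(53)
        boot = []
        for _ in range(500):
            idx = rng.integers(0, 650, size=650)
            Xb, yb = X.iloc[idx].reset_index(drop=True), masked.ir[idx]
            if Xb["vat"].notna().sum() < 10:
                continue
            boot.append(cls().fit(Xb, yb).coef_)
        ratio = rec.se / np.std(boot, ddof=1)
        assert 0.9 < ratio < 1.1


class TestPooling:
    def test_equal_variances_simple_average(self):
        beta, se = pool_inverse_variance(0.1, 0.04, 0.3, 0.04)
        assert beta == pytest.approx(0.2)
        assert se == pytest.approx(np.sqrt(0.02))

    def test_dominant_precision(self):
        beta, _ = pool_inverse_variance(0.1, 1e-12, 0.9, 1.0)
        assert beta == pytest.approx(0.1, abs=1e-6)

    def test_nonconverged_input_propagates(self):
        ok = EstimateRecord.from_beta_se("ivs_restricted", "random", 0.2, 0.1)
        bad = EstimateRecord.failed("standard_rc", "random")
        rec = est_efficient_rc(ok, bad)
        assert not rec.converged and np.isnan(rec.beta_hat)

    def test_record_pooling_matches_arithmetic(self):
        r1 = EstimateRecord.from_beta_se("ivs_restricted", "random", 0.1, 0.2)
        r2 = EstimateRecord.from_beta_se("standard_rc", "random", 0.3, 0.2)
        rec = est_efficient_rc(r1, r2)
        assert rec.method == "efficient_rc"
        assert rec.beta_hat == pytest.approx(0.2)
        assert rec.se == pytest.approx(np.sqrt(0.02))


class TestWaldInterval:
    def test_ci_bounds_are_pm_1_96_se(self, small_cohort):
        _params, cohort = small_cohort
        rec = est_uncorrected(cohort)
        assert rec.ci_low == pytest.approx(rec.beta_hat - 1.96 * rec.se)
        assert rec.ci_high == pytest.approx(rec.beta_hat + 1.96 * rec.se)


class TestBetaToPercent:
    @pytest.mark.parametrize("b, expected", [
        (0.0, 0.0),
        (np.log(1.27), 27.0),
        (0.2, 22.140275816),
    ])
    def test_values(self, b, expected):
        assert beta_to_percent(b) == pytest.approx(expected, rel=1e-9)


class TestSklearnInterface:
    def test_clone_and_params_round_trip(self):
        from sklearn.base import clone
        est = ValidationRegressionCalibration(confounders=("sex", "age"))
        cloned = clone(est)
        assert cloned.get_params()["confounders"] == ("sex", "age")

    def test_fitted_attributes(self, small_cohort):
        _params, cohort = small_cohort
        sel = select_random(cohort.n, 260, seed=2)
        masked = mask_nonvalidation(cohort, sel)
        est = EfficientRegressionCalibration().fit(
            design_frame(masked), masked.ir)
        assert est.converged_
        assert est.se_ > 0
        lo, hi = est.conf_int()
        assert lo < est.coef_ < hi
        assert est.restricted_.coef_ != est.standard_.coef_

    def test_missing_column_message(self):
        X = pd.DataFrame({"wc": [1.0, 2.0], "sex": [0, 1]})
        with pytest.raises(ValueError, match="missing columns"):
            UncorrectedRegression().fit(X, np.zeros(2))

    def test_validation_sample_from_nan_pattern(self, small_cohort):
        # rows with observed gold standard define the validation sample
        _params, cohort = small_cohort
        sel = select_random(cohort.n, 260, seed=3)
        masked = mask_nonvalidation(cohort, sel)
        est = ValidationSubsetRegression().fit(design_frame(masked), masked.ir)
        rec = est_ivs_restricted(cohort, sel)
        assert est.coef_ == pytest.approx(rec.beta_hat, rel=1e-12)
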
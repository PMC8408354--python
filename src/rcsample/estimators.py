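"""Estimators of an exposure-outcome association under exposure
measurement error with an internal validation sample.

Five analyses, each returning a point estimate of the exposure coefficient
beta, a model-based standard error and a Wald 95% confidence interval:

``uncorrected``
    OLS of the outcome on the error-prone substitute plus confounders,
    ignoring measurement error (attenuated under nondifferential error).
``ivs_restricted``
    OLS of the outcome on the gold standard plus confounders, restricted to
    the validation sample (unbiased under random sampling; subject to
    collider stratification bias when selection depends on the substitute
    and error is differential).
``standard_rc``
    Standard regression calibration: the substitute is replaced for *all*
    rows by the predicted conditional mean of the gold standard given the
    substitute and confounders, estimated in the validation sample.
``validation_rc``
    Validation regression calibration: observed gold-standard values inside
    the validation sample, calibration predictions outside it.
``efficient_rc``
    Inverse-variance-weighted pooling of the ivs_restricted and standard_rc
    estimates.

The two-step calibration estimators propagate first-stage uncertainty into
the standard error via a stacked estimating-equations sandwich (multivariate
delta method) over the joint (calibration, outcome) parameter vector; see
:func:`rc_sandwich_se` for the construction.  The pooled estimator uses
simple inverse-variance weights, ignoring the correlation between its two
components — a known source of slight undercoverage.

The estimator classes follow the scikit-learn protocol (``fit(X, y)``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
interoperate with sklearn model selection; thin ``est_*`` functions wrap
them for use with :class:`~rcsample.dgm.CohortData`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dgm import CohortData
from .sampling import ValidationSelection, mask_nonvalidation

__all__ = [
    "EstimateRecord",
    "RankDeficiencyError",
    "fit_linear",
    "rc_sandwich_se",
    "UncorrectedRegression",
    "ValidationSubsetRegression",
    "StandardRegressionCalibration",
    "ValidationRegressionCalibration",
    "EfficientRegressionCalibration",
    "est_uncorrected",
    "est_ivs_restricted",
    "est_standard_rc",
    "est_validation_rc",
    "est_efficient_rc",
    "pool_inverse_variance",
    "beta_to_percent",
    "METHODS",
]

METHODS = ("uncorrected", "ivs_restricted", "standard_rc",
           "validation_rc", "efficient_rc")

Z_CRIT = 1.96  # Wald 95% critical value


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; the fit cannot be completed."""


@dataclass(frozen=True)
class EstimateRecord:
    """One analysis's result: estimate, SE and Wald 95% CI for beta."""

    method: str
    strategy: str | None
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool = True

    @classmethod
    def from_beta_se(cls, method: str, strategy: str | None,
                     beta_hat: float, se: float,
                     converged: bool = True) -> "EstimateRecord":
        return cls(method=method, strategy=strategy, beta_hat=beta_hat,
                   se=se, ci_low=beta_hat - Z_CRIT * se,
                   ci_high=beta_hat + Z_CRIT * se, converged=converged)

    @classmethod
    def failed(cls, method: str, strategy: str | None) -> "EstimateRecord":
        return cls(method=method, strategy=strategy, beta_hat=np.nan,
                   se=np.nan, ci_low=np.nan, ci_high=np.nan, converged=False)


def fit_linear(outcome: np.ndarray,
               design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares with the classical model-based covariance.

    Returns ``(coefficients, covariance)`` where the covariance is
    sigma^2 (X'X)^{-1} with the unbiased residual-variance estimator
    RSS/(n - p).  Raises :class:`RankDeficiencyError` when the design is
    rank deficient or has fewer than p + 1 rows.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise RankDeficiencyError(f"need more than {p} rows, got {n}")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise RankDeficiencyError(
            f"design has rank {rank} < {p} columns")
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, cov


def rc_sandwich_se(
    C: np.ndarray,
    D: np.ndarray,
    val: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
    beta_x: float,
    hybrid: bool,
    x_index: int = 1,
) -> float:
    """Sandwich SE for the exposure coefficient of a two-step calibration fit.

    The stacked moment conditions are

        g1_i = v_i * c_i * (gold_i - c_i' gamma)          (calibration)
        g2_i = d_i * (y_i - d_i' beta)                    (outcome)

    with c_i a row of the calibration design ``C`` (intercept, substitute,
    confounders), d_i a row of the outcome design ``D`` whose exposure
    column is the calibration prediction (standard RC) or the hybrid
    exposure (validation RC), v_i the validation indicator ``val``, and
    ``r1``/``r2`` the stage-1/stage-2 residuals (r1 zeroed outside the
    validation sample).  The covariance of the stacked estimator is
    A^{-1} B A^{-T} with A the Jacobian of the summed moments and B their
    outer-product sum; the dependence of d_i on gamma enters A through the
    chain rule, weighted by w_i = 1 for standard RC and w_i = 1 - v_i for
    the hybrid exposure (observed gold-standard values do not move with the
    calibration fit).
    """
    n, p = C.shape
    q = D.shape[1]
    Cv = C[val]
    w = np.ones(n) if not hybrid else (~val).astype(float)

    A11 = -(Cv.T @ Cv)
    A22 = -(D.T @ D)
    A21 = -beta_x * (D.T @ (w[:, None] * C))
    A21[x_index] += (w * r2) @ C

    r1v = r1[val]
    B11 = (Cv * (r1v * r1v)[:, None]).T @ Cv
    B22 = (D * (r2 * r2)[:, None]).T @ D
    B21 = (D[val] * (r1v * r2[val])[:, None]).T @ Cv

    A = np.zeros((p + q, p + q))
    A[:p, :p] = A11
    A[p:, :p] = A21
    A[p:, p:] = A22
    B = np.zeros((p + q, p + q))
    B[:p, :p] = B11
    B[p:, :p] = B21
    B[:p, p:] = B21.T
    B[p:, p:] = B22

    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv.T
    var = V[p + x_index, p + x_index]
    if not np.isfinite(var) or var <= 0:
        raise RankDeficiencyError("sandwich variance not positive definite")
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# numpy cores shared by the estimator classes and the simulation engine

def ols_beta_se(y: np.ndarray, X: np.ndarray,
                x_index: int = 1) -> tuple[float, float]:
    coef, cov = fit_linear(y, X)
    return float(coef[x_index]), float(np.sqrt(cov[x_index, x_index]))


def rc_beta_se(
    y: np.ndarray,
    wc: np.ndarray,
    gold: np.ndarray,
    Z: np.ndarray,
    val: np.ndarray,
    hybrid: bool,
) -> tuple[float, float, np.ndarray]:
    """Two-step regression-calibration fit.

    Returns ``(beta_hat, se, gamma)`` with ``gamma`` the calibration
    coefficients.  ``gold`` only needs finite values where ``val`` is True.
    """
    C = np.column_stack([np.ones(len(y)), wc, Z])
    Cv = C[val]
    gamma, _, rank, _ = np.linalg.lstsq(Cv, gold[val], rcond=None)
    if rank < C.shape[1]:
        raise RankDeficiencyError("calibration design is rank deficient")
    xhat = C @ gamma
    expo = np.where(val, gold, xhat) if hybrid else xhat
    D = np.column_stack([np.ones(len(y)), expo, Z])
    beta, _, rank2, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank2 < D.shape[1]:
        raise RankDeficiencyError("outcome design is rank deficient")
    r1 = np.zeros(len(y))
    r1[val] = gold[val] - Cv @ gamma
    r2 = y - D @ beta
    se = rc_sandwich_se(C, D, val, r1, r2, float(beta[1]), hybrid)
    return float(beta[1]), se, gamma


def pool_inverse_variance(b1: float, v1: float,
                          b2: float, v2: float) -> tuple[float, float]:
    """Inverse-variance-weighted mean of two estimates and its SE."""
    if v1 <= 0 or v2 <= 0:
        raise ValueError("variances must be positive")
    w1, w2 = 1.0 / v1, 1.0 / v2
    beta = (b1 * w1 + b2 * w2) / (w1 + w2)
    return beta, float(np.sqrt(1.0 / (w1 + w2)))


def beta_to_percent(beta_hat: float) -> float:
    """Express a log-scale coefficient as a percentage difference in the
    outcome per unit (SD) of exposure: 100*(exp(beta) - 1)."""
    return 100.0 * (np.exp(beta_hat) - 1.0)


# ---------------------------------------------------------------------------
# scikit-learn estimator layer

class _MeasurementErrorRegressor(BaseEstimator):
    """Shared plumbing: column resolution, fit bookkeeping, CI."""

    _method = ""

    def __init__(self, exposure_col="wc", gold_col="vat",
                 confounders=("sex", "age", "tbf")):
        self.exposure_col = exposure_col
        self.gold_col = gold_col
        self.confounders = confounders

    def _resolve(self, X: pd.DataFrame, y) -> dict:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a DataFrame with named exposure/confounder "
                "columns; got " + type(X).__name__)
        needed = [self.exposure_col, *self.confounders]
        if self.gold_col in X.columns:
            needed.append(self.gold_col)
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing columns {missing}")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        wc = X[self.exposure_col].to_numpy(dtype=float)
        Z = X[list(self.confounders)].to_numpy(dtype=float)
        gold = (X[self.gold_col].to_numpy(dtype=float)
                if self.gold_col in X.columns
                else np.full(len(X), np.nan))
        val = np.isfinite(gold)
        return {"y": y, "wc": wc, "Z": Z, "gold": gold, "val": val}

    def _finish(self, beta: float, se: float) -> "_MeasurementErrorRegressor":
        self.coef_ = beta
        self.se_ = se
        self.ci_ = (beta - Z_CRIT * se, beta + Z_CRIT * se)
        self.converged_ = True
        return self

    def conf_int(self) -> tuple[float, float]:
        return self.ci_

    def record(self, strategy: str | None = None) -> EstimateRecord:
        return EstimateRecord.from_beta_se(
            self._method, strategy, self.coef_, self.se_, self.converged_)


class UncorrectedRegression(_MeasurementErrorRegressor):
    """OLS of the outcome on the error-prone substitute, ignoring error."""

    _method = "uncorrected"

    def fit(self, X, y):
        d = self._resolve(X, y)
        design = np.column_stack([np.ones(len(d["y"])), d["wc"], d["Z"]])
        beta, se = ols_beta_se(d["y"], design)
        return self._finish(beta, se)


class ValidationSubsetRegression(_MeasurementErrorRegressor):
    """OLS on the gold standard, restricted to rows where it is observed."""

    _method = "ivs_restricted"

    def fit(self, X, y):
        d = self._resolve(X, y)
        val = d["val"]
        if not val.any():
            raise ValueError("no rows with an observed gold standard")
        design = np.column_stack(
            [np.ones(int(val.sum())), d["gold"][val], d["Z"][val]])
        beta, se = ols_beta_se(d["y"][val], design)
        return self._finish(beta, se)


class StandardRegressionCalibration(_MeasurementErrorRegressor):
    """Two-step regression calibration with predictions for all rows.

    Fitted attributes include ``calibration_coef_`` (intercept, substitute,
    confounders) from the first stage.
    """

    _method = "standard_rc"
    _hybrid = False

    def fit(self, X, y):
        d = self._resolve(X, y)
        beta, se, gamma = rc_beta_se(
            d["y"], d["wc"], d["gold"], d["Z"], d["val"], self._hybrid)
        self.calibration_coef_ = gamma
        return self._finish(beta, se)


class ValidationRegressionCalibration(StandardRegressionCalibration):
    """Regression calibration with a hybrid exposure: observed gold-standard
    values inside the validation sample, predictions outside it."""

    _method = "validation_rc"
    _hybrid = True


class EfficientRegressionCalibration(_MeasurementErrorRegressor):
    """Inverse-variance pooling of the validation-subset and standard-RC
    fits.  Component estimators are exposed as ``restricted_`` and
    ``standard_`` after fitting."""

    _method = "efficient_rc"

    def fit(self, X, y):
        self.restricted_ = ValidationSubsetRegression(
            self.exposure_col, self.gold_col, self.confounders).fit(X, y)
        self.standard_ = StandardRegressionCalibration(
            self.exposure_col, self.gold_col, self.confounders).fit(X, y)
        beta, se = pool_inverse_variance(
            self.restricted_.coef_, self.restricted_.se_ ** 2,
            self.standard_.coef_, self.standard_.se_ ** 2)
        return self._finish(beta, se)


# ---------------------------------------------------------------------------
# CohortData-facing wrappers

def design_frame(cohort: CohortData) -> pd.DataFrame:
    """Estimator-ready frame: wc, confounders, and vat masked to the
    validation sample (NaN elsewhere)."""
    vat = np.where(cohort.in_validation, cohort.vat, np.nan)
    return pd.DataFrame({"wc": cohort.wc, "sex": cohort.sex,
                         "age": cohort.age, "tbf": cohort.tbf, "vat": vat})


def _masked(cohort: CohortData,
            sel: ValidationSelection | None) -> CohortData:
    return cohort if sel is None else mask_nonvalidation(cohort, sel)


def est_uncorrected(cohort: CohortData) -> EstimateRecord:
    try:
        est = UncorrectedRegression().fit(design_frame(cohort), cohort.ir)
    except (RankDeficiencyError, np.linalg.LinAlgError):
        return EstimateRecord.failed("uncorrected", None)
    return est.record(None)


def est_ivs_restricted(cohort: CohortData,
                       sel: ValidationSelection | None = None
                       ) -> EstimateRecord:
    c = _masked(cohort, sel)
    strategy = sel.strategy if sel is not None else None
    try:
        est = ValidationSubsetRegression().fit(design_frame(c), c.ir)
    except (RankDeficiencyError, np.linalg.LinAlgError):
        return EstimateRecord.failed("ivs_restricted", strategy)
    return est.record(strategy)


def est_standard_rc(cohort: CohortData,
                    sel: ValidationSelection | None = None
                    ) -> EstimateRecord:
    c = _masked(cohort, sel)
    strategy = sel.strategy if sel is not None else None
    try:
        est = StandardRegressionCalibration().fit(design_frame(c), c.ir)
    except (RankDeficiencyError, np.linalg.LinAlgError):
        return EstimateRecord.failed("standard_rc", strategy)
    return est.record(strategy)


def est_validation_rc(cohort: CohortData,
                      sel: ValidationSelection | None = None
                      ) -> EstimateRecord:
    c = _masked(cohort, sel)
    strategy = sel.strategy if sel is not None else None
    try:
        est = ValidationRegressionCalibration().fit(design_frame(c), c.ir)
    except (RankDeficiencyError, np.linalg.LinAlgError):
        return EstimateRecord.failed("validation_rc", strategy)
    return est.record(strategy)


def est_efficient_rc(rec_restricted: EstimateRecord,
                     rec_standard: EstimateRecord) -> EstimateRecord:
    """Pool the validation-subset and standard-RC records by inverse
    variance.  Non-converged inputs yield a non-converged output."""
    strategy = rec_restricted.strategy or rec_standard.strategy
    if not (rec_restricted.converged and rec_standard.converged):
        return EstimateRecord.failed("efficient_rc", strategy)
    beta, se = pool_inverse_variance(
        rec_restricted.beta_hat, rec_restricted.se ** 2,
        rec_standard.beta_hat, rec_standard.se ** 2)
    return EstimateRecord.from_beta_se("efficient_rc", strategy, beta, se)
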
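"""Synthetic cohort generation for the measurement-error simulation study.

The data-generating mechanism emulates a cross-sectional obesity cohort in
which visceral adipose tissue (VAT, the gold-standard exposure) is expensive
to measure and waist circumference (WC) serves as an error-prone substitute,
with insulin resistance (IR) as the continuous outcome and sex, age and total
body fat (TBF) as confounders.  All continuous measures live on a
standardized synthetic scale:

    sex ~ Bernoulli(0.5)
    age ~ Uniform(45, 65)
    TBF | sex, age ~ Normal(-2 + sex + 0.01*age, var=0.5)
    VAT = 0.4 - 2*sex + 0.01*age + 0.9*TBF + (eps - E[eps]),
          eps ~ Gamma(shape=6*lam, scale=sqrt(0.5/(6*lam)))
    WC  | VAT ~ Normal(theta*VAT, var=tau^2)              (linear)
                Normal(theta*t(VAT), var=tau^2)           (nonlinear)
                Normal(theta*VAT + tau*U, var=tau^2)      (differential)
    IR  | VAT, sex, age, TBF
        ~ Normal(0.5 + beta*VAT - 0.5*sex + 0.01*age + 0.3*TBF
                 [+ sqrt(0.3)*U], var=0.3)

Second parameters of all normal distributions are variances.  The gamma
residual eps is centered by its mean 6*lam*sqrt(0.5/(6*lam)), so its variance
is exactly 0.5 for every lam while its skewness 2/sqrt(6*lam) is free —
skewness of the gold standard's residuals is a design factor of the study
without touching the marginal mean or variance.  U ~ Bernoulli(0.5) is a
latent variable shared by WC and IR in the differential-error variant,
making the substitute's error depend on the outcome.

The nonlinear variant uses the sign-preserving square root
t(v) = sign(v)*sqrt(|v|), since VAT takes negative values on the
standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DGMParams",
    "CohortData",
    "ScenarioConfig",
    "lambda_from_skewness",
    "skewness_from_lambda",
    "vat_variance_analytic",
    "tau_closed_form",
    "tau_from_r2",
    "generate_cohort",
    "scenario_grid",
    "DEFAULT_R2_GRID",
    "DEFAULT_SKEWNESS_GRID",
    "DIFFERENTIAL_TAU",
]

#: factorial design levels for the explained variance of WC given VAT
DEFAULT_R2_GRID = (0.2, 0.4, 0.6, 0.8, 0.9)
#: factorial design levels for the skewness of the VAT residual
DEFAULT_SKEWNESS_GRID = (0.1, 1.0, 1.5, 3.0)
#: residual SD of WC given VAT in the differential-error scenario
#: (corresponds to R^2 = 0.8 under the linear mechanism)
DIFFERENTIAL_TAU = 0.44

# fixed structural coefficients of the mechanism
_THETA_DEFAULT = 0.8
_BETA_DEFAULT = 0.2


class InvalidParameterError(ValueError):
    """A DGM or scenario parameter violates its domain."""


@dataclass(frozen=True)
class DGMParams:
    """Parameters of the data-generating mechanism.

    Attributes
    ----------
    beta : float
        Conditional effect of VAT on IR — the estimand (default 0.2).
    theta : float
        Calibration slope of WC on (transformed) VAT (default 0.8).
    tau : float
        Residual SD of WC given VAT, >= 0.
    lam : float
        Gamma shape control for the VAT residual; shape = 6*lam,
        scale = sqrt(0.5/(6*lam)), so Var(eps) = 0.5 and
        skew(eps) = 2/sqrt(6*lam).
    linear : bool
        Linear (True) vs sign-preserving square-root (False) WC mean model.
    differential : bool
        Include the shared latent U in both WC and IR.
    n : int
        Cohort size.
    """

    beta: float = _BETA_DEFAULT
    theta: float = _THETA_DEFAULT
    tau: float = 0.44
    lam: float = 2.0 / 3.0
    linear: bool = True
    differential: bool = False
    n: int = 650

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InvalidParameterError(f"tau must be >= 0, got {self.tau}")
        if self.lam <= 0:
            raise InvalidParameterError(f"lam must be > 0, got {self.lam}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    @property
    def gamma_shape(self) -> float:
        return 6.0 * self.lam

    @property
    def gamma_scale(self) -> float:
        return float(np.sqrt(0.5 / (6.0 * self.lam)))


@dataclass
class CohortData:
    """One generated cohort, column vectors of identical length.

    ``vat`` is fully observed at generation time; restricting it to a
    validation subsample is an explicit masking step (see
    :func:`rcsample.sampling.mask_nonvalidation`), after which masked
    entries are NaN and ``in_validation`` flags the observed rows.
    ``u`` is the latent Bernoulli variable of the differential-error
    variant and is constant 0 otherwise.
    """

    sex: np.ndarray
    age: np.ndarray
    tbf: np.ndarray
    vat: np.ndarray
    wc: np.ndarray
    ir: np.ndarray
    u: np.ndarray
    in_validation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.sex)
        if self.in_validation is None:
            self.in_validation = np.ones(n, dtype=bool)
        arrays = (self.sex, self.age, self.tbf, self.vat, self.wc,
                  self.ir, self.u, self.in_validation)
        if len({len(a) for a in arrays}) != 1:
            raise ValueError("all cohort columns must have identical length")

    @property
    def n(self) -> int:
        return len(self.sex)

    def to_frame(self) -> pd.DataFrame:
        """Export as a tidy DataFrame (masked vat appears as NaN)."""
        return pd.DataFrame(
            {
                "sex": self.sex,
                "age": self.age,
                "tbf": self.tbf,
                "vat": self.vat,
                "wc": self.wc,
                "ir": self.ir,
                "u": self.u,
                "in_validation": self.in_validation,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def copy(self) -> "CohortData":
        return CohortData(
            sex=self.sex.copy(), age=self.age.copy(), tbf=self.tbf.copy(),
            vat=self.vat.copy(), wc=self.wc.copy(), ir=self.ir.copy(),
            u=self.u.copy(), in_validation=self.in_validation.copy(),
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial simulation design."""

    r2_target: float = 0.8
    skewness: float = 0.1
    linear: bool = True
    differential: bool = False
    val_fraction: float = 0.40
    n: int = 650
    n_reps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_target < 1:
            raise InvalidParameterError(
                f"r2_target must be in (0,1), got {self.r2_target}")
        if self.skewness <= 0:
            raise InvalidParameterError(
                f"skewness must be > 0, got {self.skewness}")
        if not 0 < self.val_fraction <= 1:
            raise InvalidParameterError(
                f"val_fraction must be in (0,1], got {self.val_fraction}")
        if self.n < 1 or self.n_reps < 1:
            raise InvalidParameterError("n and n_reps must be >= 1")

    def label(self) -> str:
        kind = "diff" if self.differential else (
            "lin" if self.linear else "nonlin")
        return (f"r2={self.r2_target:g}_s={self.skewness:g}_{kind}"
                f"_f={self.val_fraction:g}")


def lambda_from_skewness(s: float) -> float:
    """Gamma shape control lam achieving residual skewness ``s``.

    A gamma with shape ``6*lam`` has skewness ``2/sqrt(6*lam)``; inverting
    gives ``lam = 2/(3*s**2)``, the unique solution.
    """
    if s <= 0:
        raise InvalidParameterError(f"skewness must be > 0, got {s}")
    return 2.0 / (3.0 * s * s)


def skewness_from_lambda(lam: float) -> float:
    """Inverse of :func:`lambda_from_skewness` (skewness of Gamma(6*lam))."""
    if lam <= 0:
        raise InvalidParameterError(f"lam must be > 0, got {lam}")
    return 2.0 / np.sqrt(6.0 * lam)


def vat_variance_analytic() -> float:
    """Marginal variance of VAT implied by the mechanism.

    VAT = 0.4 - 2*sex + 0.01*age + 0.9*TBF + eps_c with
    TBF = -2 + sex + 0.01*age + e_t, e_t ~ N(0, 0.5).  Collecting terms,
    the sex coefficient is -1.1, the age coefficient 0.019, plus
    0.9*e_t and the centered gamma residual (variance 0.5):

        Var = 1.1^2 * 0.25 + 0.019^2 * (20^2/12) + 0.81*0.5 + 0.5
    """
    var_sex = 0.25
    var_age = 400.0 / 12.0
    return (-1.1) ** 2 * var_sex + 0.019 ** 2 * var_age + 0.81 * 0.5 + 0.5


def tau_closed_form(r2: float, theta: float = _THETA_DEFAULT) -> float:
    """Closed-form tau for the *linear* mechanism.

    For WC = theta*VAT + e, the R^2 of the simple regression of WC on VAT is
    theta^2 Var(VAT) / (theta^2 Var(VAT) + tau^2); solving for tau gives
    tau^2 = theta^2 * Var(VAT) * (1 - R^2) / R^2.
    """
    if not 0 < r2 < 1:
        raise InvalidParameterError(f"r2 must be in (0,1), got {r2}")
    return float(np.sqrt(theta ** 2 * vat_variance_analytic() * (1 - r2) / r2))


def _signed_sqrt(v: np.ndarray) -> np.ndarray:
    """Sign-preserving square root; VAT can be negative on this scale."""
    return np.sign(v) * np.sqrt(np.abs(v))


def tau_from_r2(
    r2: float,
    params: DGMParams | None = None,
    n_cal: int = 1_000_000,
    seed: int | np.random.SeedSequence = 0,
    tol: float = 1e-3,
) -> float:
    """Solve for the residual SD tau achieving a target R^2 of WC on VAT.

    A single large calibration cohort of size ``n_cal`` is generated under
    ``params``; writing WC(tau) = m + tau*w with m the mean signal
    (theta*VAT or theta*t(VAT), plus U in the differential variant where the
    noise w absorbs U as well) and w a fixed standard-normal draw, the
    sample R^2 of the simple linear regression of WC on VAT is an explicit,
    strictly decreasing function of tau:

        R^2(tau) = Cov(m + tau*w, VAT)^2 / (Var(m + tau*w) * Var(VAT))

    computed from five base moments; the root is found by Brent's method.

    Raises a diagnostic error if the target cannot be bracketed, reporting
    the achievable R^2 range.
    """
    if not 0 < r2 < 1:
        raise InvalidParameterError(f"r2 must be in (0,1), got {r2}")
    if params is None:
        params = DGMParams()

    rng = np.random.default_rng(seed)
    base = replace(params, tau=0.0, n=n_cal)
    cohort = _draw_structural(base, n_cal, rng)
    vat = cohort["vat"]
    m = params.theta * (vat if params.linear else _signed_sqrt(vat))
    w = rng.standard_normal(n_cal)
    if params.differential:
        # the latent U enters the WC mean with coefficient tau as well
        w = w + cohort["u"]

    vat_c = vat - vat.mean()
    m_c = m - m.mean()
    w_c = w - w.mean()
    cov_mv = float(m_c @ vat_c) / n_cal
    cov_wv = float(w_c @ vat_c) / n_cal
    var_m = float(m_c @ m_c) / n_cal
    var_w = float(w_c @ w_c) / n_cal
    cov_mw = float(m_c @ w_c) / n_cal
    var_v = float(vat_c @ vat_c) / n_cal

    def r2_of(tau: float) -> float:
        cov = cov_mv + tau * cov_wv
        var_wc = var_m + 2 * tau * cov_mw + tau * tau * var_w
        return cov * cov / (var_wc * var_v)

    r2_hi = r2_of(0.0)
    if r2 > r2_hi + tol:
        raise InvalidParameterError(
            f"target R^2={r2} unattainable: mechanism's maximum is "
            f"{r2_hi:.4f} (nonlinear signal caps the simple-regression R^2)")
    hi = 1.0
    while r2_of(hi) > r2 and hi < 1e6:
        hi *= 2.0
    if r2_of(hi) > r2:
        raise InvalidParameterError(
            f"could not bracket tau: achieved R^2 range "
            f"[{r2_of(hi):.4f}, {r2_hi:.4f}] does not contain {r2}")
    if r2 >= r2_hi:  # within tol of the zero-noise limit
        return 0.0
    tau = optimize.brentq(lambda t: r2_of(t) - r2, 0.0, hi, xtol=1e-10)
    return float(tau)


def _draw_structural(params: DGMParams, n: int,
                     rng: np.random.Generator) -> dict:
    """Draw sex, age, TBF, VAT and U (everything upstream of WC and IR)."""
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    age = rng.uniform(45.0, 65.0, size=n)
    tbf = -2.0 + sex + 0.01 * age + rng.normal(0.0, np.sqrt(0.5), size=n)
    eps = rng.gamma(params.gamma_shape, params.gamma_scale, size=n)
    eps_mean = params.gamma_shape * params.gamma_scale
    vat = 0.4 - 2.0 * sex + 0.01 * age + 0.9 * tbf + (eps - eps_mean)
    if params.differential:
        u = rng.binomial(1, 0.5, size=n).astype(float)
    else:
        u = np.zeros(n)
    return {"sex": sex, "age": age, "tbf": tbf, "vat": vat, "u": u}


def generate_cohort(
    params: DGMParams,
    n: int | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> CohortData:
    """Generate one cohort under the mechanism described in the module docs."""
    if n is None:
        n = params.n
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    s = _draw_structural(params, n, rng)
    sex, age, tbf, vat, u = s["sex"], s["age"], s["tbf"], s["vat"], s["u"]

    wc_mean = params.theta * (vat if params.linear else _signed_sqrt(vat))
    if params.differential:
        wc_mean = wc_mean + params.tau * u
    wc = wc_mean + params.tau * rng.standard_normal(n)

    ir_mean = (0.5 + params.beta * vat - 0.5 * sex + 0.01 * age + 0.3 * tbf)
    if params.differential:
        ir_mean = ir_mean + np.sqrt(0.3) * u
    ir = ir_mean + np.sqrt(0.3) * rng.standard_normal(n)

    return CohortData(sex=sex, age=age, tbf=tbf, vat=vat, wc=wc, ir=ir, u=u)


def scenario_grid(
    r2: tuple[float, ...] = DEFAULT_R2_GRID,
    skewness: tuple[float, ...] = DEFAULT_SKEWNESS_GRID,
    linear: tuple[bool, ...] = (True, False),
    differential: tuple[bool, ...] = (False,),
    val_fraction: tuple[float, ...] = (0.40,),
    n: int = 650,
    n_reps: int = 5000,
    seed: int = 0,
) -> list[ScenarioConfig]:
    """Expand factor levels to the full-factorial list of scenarios.

    The default levels give the 5 x 4 x 2 = 40-scenario nondifferential grid
    at a 40% validation fraction.
    """
    grid = [
        ScenarioConfig(r2_target=r, skewness=s, linear=li, differential=d,
                       val_fraction=f, n=n, n_reps=n_reps, seed=seed)
        for f in val_fraction
        for d in differential
        for li in linear
        for s in skewness
        for r in r2
    ]
    if not grid:
        raise InvalidParameterError("scenario grid is empty")
    return grid
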
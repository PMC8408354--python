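"""Internal-validation sampling strategies.

Three designs for choosing the subsample in which the gold-standard exposure
is measured: simple random sampling, stratified random sampling over
equal-width strata of the error-prone measure, and extremes sampling (the
lowest and highest tails of the error-prone measure).  Selecting on the
error-prone measure is deliberate — it is the only exposure information
available before the validation measurements are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgm import CohortData, InvalidParameterError

__all__ = [
    "ValidationSelection",
    "validation_size",
    "select_random",
    "select_extremes",
    "select_stratified",
    "select",
    "mask_nonvalidation",
    "STRATEGIES",
]

STRATEGIES = ("random", "stratified", "extremes")


@dataclass(frozen=True)
class ValidationSelection:
    """A chosen validation subsample: strategy label and row indices."""

    strategy: str
    indices: np.ndarray
    m: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        object.__setattr__(self, "indices", idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if len(idx) != self.m:
            raise ValueError(
                f"selection has {len(idx)} indices but m={self.m}")

    def mask(self, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        out[self.indices] = True
        return out


def validation_size(n: int, fraction: float) -> int:
    """Target validation-sample size: round(fraction*n), at least 1.

    Uses round-half-to-even on the exact product, so e.g. n=650 at 40%
    gives 260 and at 10% gives 65.
    """
    if not 0 < fraction <= 1:
        raise InvalidParameterError(
            f"fraction must be in (0,1], got {fraction}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    m = int(round(fraction * n))
    return max(m, 1)


def _check_m(n: int, m: int) -> None:
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    if m > n:
        raise InvalidParameterError(f"m={m} exceeds cohort size n={n}")


def select_random(
    n: int, m: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ValidationSelection:
    """Simple random sample of m rows without replacement."""
    _check_m(n, m)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.choice(n, size=m, replace=False)
    return ValidationSelection("random", np.sort(idx), m)


def select_extremes(wc: np.ndarray, m: int) -> ValidationSelection:
    """The floor(m/2) lowest and ceil(m/2) highest values of ``wc``.

    Deterministic given the data; ties are broken by original row order
    (stable sort).
    """
    wc = np.asarray(wc, dtype=float)
    n = len(wc)
    _check_m(n, m)
    order = np.argsort(wc, kind="stable")
    n_low = m // 2
    n_high = m - n_low
    idx = np.concatenate([order[:n_low], order[n - n_high:]])
    return ValidationSelection("extremes", np.sort(idx), m)


def select_stratified(
    wc: np.ndarray,
    m: int,
    k: int = 10,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ValidationSelection:
    """Stratified random sample over k equal-width strata of ``wc``.

    Strata are equal-width intervals spanning [min(wc), max(wc)], half-open
    [a, b) with the last interval closed so the maximum is always assigned.
    The base quota is an integer split of m over the k strata (remainder to
    the lowest-indexed strata).  A stratum with fewer members than its quota
    contributes all of them; the resulting deficit is redistributed one unit
    at a time, round-robin over the strata with remaining capacity in order
    of decreasing capacity, until exactly m rows are allocated.  Within each
    stratum the rows are a simple random sample without replacement.
    """
    wc = np.asarray(wc, dtype=float)
    n = len(wc)
    _check_m(n, m)
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    lo, hi = wc.min(), wc.max()
    if hi > lo:
        edges = np.linspace(lo, hi, k + 1)
        # interior edges only: values == an edge go to the upper stratum,
        # and the global max lands in stratum k-1 (closed last interval)
        strata = np.searchsorted(edges[1:-1], wc, side="right")
    else:
        strata = np.zeros(n, dtype=np.intp)  # constant wc: one stratum

    counts = np.bincount(strata, minlength=k)
    base, rem = divmod(m, k)
    quota = np.full(k, base, dtype=np.intp)
    quota[:rem] += 1
    alloc = np.minimum(quota, counts)

    deficit = m - int(alloc.sum())
    while deficit > 0:
        capacity = counts - alloc
        # one unit per eligible stratum per pass, largest capacity first
        order = np.lexsort((np.arange(k), -capacity))
        progressed = False
        for s in order:
            if deficit == 0:
                break
            if capacity[s] > 0:
                alloc[s] += 1
                deficit -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by _check_m
            raise InvalidParameterError("insufficient capacity to reach m")

    picked = []
    for s in range(k):
        if alloc[s] == 0:
            continue
        members = np.flatnonzero(strata == s)
        if alloc[s] == len(members):
            picked.append(members)
        else:
            picked.append(rng.choice(members, size=alloc[s], replace=False))
    idx = np.sort(np.concatenate(picked))
    return ValidationSelection("stratified", idx, m)


def select(
    strategy: str,
    wc: np.ndarray,
    m: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    k: int = 10,
) -> ValidationSelection:
    """Dispatch on strategy name ('random', 'stratified', 'extremes')."""
    if strategy == "random":
        return select_random(len(wc), m, seed)
    if strategy == "stratified":
        return select_stratified(wc, m, k=k, seed=seed)
    if strategy == "extremes":
        return select_extremes(wc, m)
    raise InvalidParameterError(
        f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def mask_nonvalidation(cohort: CohortData,
                       sel: ValidationSelection) -> CohortData:
    """Remove the gold-standard measure outside the validation sample.

    Returns a copy with ``vat`` set to NaN for unselected rows and
    ``in_validation`` set from the selection.
    """
    if len(sel.indices) == 0:
        raise InvalidParameterError("empty validation selection")
    if sel.indices.max() >= cohort.n or sel.indices.min() < 0:
        raise InvalidParameterError("selection indices out of range")
    out = cohort.copy()
    mask = sel.mask(cohort.n)
    out.vat = np.where(mask, out.vat, np.nan)
    out.in_validation = mask
    return out
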
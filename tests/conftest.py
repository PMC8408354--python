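import numpy as np
import pytest

from rcsample.dgm import DGMParams, generate_cohort, lambda_from_skewness


@pytest.fixture(scope="session")
def big_cohort():
    """One large nondifferential cohort (moderate noise, mild skew)."""
    params = DGMParams(tau=0.44, lam=lambda_from_skewness(1.5))
    return params, generate_cohort(params, n=1_000_000, seed=101)


@pytest.fixture()
def small_cohort():
    params = DGMParams(tau=0.44, lam=lambda_from_skewness(0.1))
    return params, generate_cohort(params, n=650, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
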
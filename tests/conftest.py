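import numpy as np
import pytest

from carboxkin import (
    DEFAULT_SAMPLING_DAYS,
    FirstOrderParams,
    FitConfig,
    FitzhughParams,
    GompertzParams,
    LogisticParams,
    TimeSeries,
    eval_model,
)


@pytest.fixture(scope="session")
def sampling_days():
    return np.asarray(DEFAULT_SAMPLING_DAYS, dtype=float)


@pytest.fixture(scope="session")
def fast_fit():
    """Reduced multi-start budget for tests that fit many times."""
    return FitConfig(n_starts=8, seed=11)


def make_noiseless(params, days, system_id="sys", analyte="C6"):
    days = np.asarray(days, dtype=float)
    return TimeSeries.from_arrays(system_id, analyte, days, eval_model(params, days))


@pytest.fixture(scope="session")
def noiseless_series_factory():
    return make_noiseless


#: Well-identified truths (curves plateau within the 28-day design), one per model.
ROUNDTRIP_TRUTHS = {
    "first-order": FirstOrderParams(rho_max=1.0, k=0.2),
    "gompertz": GompertzParams(rho_max=0.05, R_max=0.006, lag=7.02),
    "logistic": LogisticParams(rho_max=0.05, R_max=0.006, lag=7.02),
    "fitzhugh": FitzhughParams(rho_max=0.08, k=0.15, n=2.471),
}
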
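import numpy as np
import pandas as pd
import pytest

from survalid.cohort import CANONICAL_COLUMNS, Cohort


def make_frame(n, rng=None, missing=None):
    """Small deterministic cohort frame with plausible covariates."""
    rng = rng or np.random.default_rng(0)
    frame = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "male": rng.integers(0, 2, n).astype(float),
            "albumin_g_l": rng.normal(42, 5, n),
            "bilirubin_umol_l": np.exp(rng.normal(np.log(10), 0.4, n)),
            "afp_ug_l": np.exp(rng.normal(np.log(9), 1.5, n)),
            "tumor_size_cm": np.exp(rng.normal(np.log(5), 0.5, n)),
            "tumor_number": 1.0 + rng.integers(0, 3, n),
            "mvi": rng.integers(0, 2, n).astype(float),
            "hep_b": rng.integers(0, 2, n).astype(float),
            "hep_c": rng.integers(0, 2, n).astype(float),
            "rfs_months": rng.uniform(0.5, 30, n),
            "event": rng.integers(0, 2, n),
        }
    )
    for (row, col) in missing or []:
        frame.loc[row, col] = np.nan
    return frame


@pytest.fixture
def small_cohort():
    return Cohort(make_frame(20), label="small")


@pytest.fixture
def sim_cox_data():
    """PH data with a known 3-covariate effect, moderate censoring."""
    rng = np.random.default_rng(7)
    n = 400
    X = rng.normal(size=(n, 3))
    beta = np.array([0.5, -0.3, 0.8])
    T = rng.exponential(1 / np.exp(X @ beta))
    C = rng.exponential(2.0, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    return X, t, e, beta
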
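import numpy as np
import pandas as pd
import pytest

from sivcmscreen.sivcm import normalize_direction
from sivcmscreen.synthetic import SivcmTruth, default_g_funcs, gen_sivcm_data


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sivcm_dataset():
    """Moderate synthetic SIVCM draw shared by estimator tests."""
    truth = SivcmTruth(
        theta_true=normalize_direction([2.0, -1.0, 0.5]).theta,
        g_funcs=default_g_funcs(5),
        noise_sd=0.3,
        n=300,
        seed=7,
    )
    return truth, gen_sivcm_data(truth)


@pytest.fixture()
def monthly_series():
    """One variable-location monthly table over 3 years, simple seasonal shape."""
    rows = []
    for year in (1990, 1991, 1992):
        for month in range(1, 13):
            val = 10.0 if month in (6, 7, 8) else (2.0 if month in (12, 1, 2) else 5.0)
            rows.append((year, month, val))
    return pd.DataFrame(rows, columns=["year", "month", "value"])
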
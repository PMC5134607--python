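import numpy as np
import pandas as pd
import pytest

from phenodesert import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wet_meadow_series():
    """Noisy full-year wet-meadow-like sub-daily series with truth."""
    df, truth = sd.generate_gcc_series(sd.WET_MEADOW_PARAMS, noise_sigma=0.003, seed=7)
    return df, truth


@pytest.fixture(scope="session")
def noiseless_daily():
    """Noiseless daily wet-meadow curve sampled at integer DOY."""
    from phenodesert.fitting import gu_model
    t = np.arange(1, 366, dtype=float)
    y = gu_model(t, **sd.WET_MEADOW_PARAMS)
    return t, y


def make_series(doy, gcc, hour=12):
    """Minimal sub-daily series DataFrame for filter tests."""
    doy = np.asarray(doy)
    ts = pd.to_datetime("2015-01-01") + pd.to_timedelta(doy - 1, unit="D") \
        + pd.to_timedelta(hour, unit="h")
    return pd.DataFrame({"timestamp": ts, "doy": doy, "roi": "test",
                         "gcc": np.asarray(gcc, dtype=float),
                         "rcc": 0.34, "bcc": 0.33, "n_pixels": 10})
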
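import numpy as np
import pandas as pd
import pytest

from nfixnet import synthetic_data as sd
from nfixnet.containers import DailyWeatherSeries, PhenologyWindows


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (95 obs, 11 sites x 2 years)."""
    return sd.gen_trial(seed=42)


@pytest.fixture(scope="session")
def sites():
    return sd.gen_sites(11, seed=0)


@pytest.fixture()
def toy_weather():
    """Ten flat days: tmean 20/amplitude 10, 2 mm rain, 5 mm ET0."""
    n = 10
    return DailyWeatherSeries(
        pd.DataFrame(
            {
                "doy": np.arange(150, 150 + n),
                "tmin": np.full(n, 15.0),
                "tmax": np.full(n, 25.0),
                "precip": np.full(n, 2.0),
                "radiation": np.full(n, 20.0),
                "et0": np.full(n, 5.0),
                "rh_mean": np.full(n, 70.0),
            }
        )
    )


@pytest.fixture()
def toy_windows():
    return PhenologyWindows(VE=150, R1=153, R4=155, R5=156, R7=159)
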
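import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thermotime.model import GENERIC_PARAMS
from thermotime.synthetic import SyntheticConfig, generate_station

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def generic_params():
    return GENERIC_PARAMS


@pytest.fixture(scope="session")
def clean_station():
    """Noise-free, all-clear synthetic station: observed hourly data is
    exactly the diurnal model at the generic parameter triple."""
    cfg = SyntheticConfig(
        overcast_fraction=0.0, hourly_noise_sigma=0.0, years=2, seed=11
    )
    return generate_station(cfg)


@pytest.fixture(scope="session")
def default_station():
    """Three years at the default study conditions (30% overcast,
    0.5 degC hourly noise)."""
    return generate_station(SyntheticConfig(seed=0, years=3))


@pytest.fixture()
def constant_daily():
    """Five identical days: the fixed point of the day-to-day recursion."""
    return pd.DataFrame(
        {
            "date": pd.date_range("2001-06-01", periods=5),
            "tmin": 10.0,
            "tmax": 20.0,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
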
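import datetime

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from tpforc.io import DailyTemperatureSeries, Phenophase, PhenologyObservationSeries
from tpforc.synthetic import WeatherGenConfig, default_truth, generate_phenology, generate_temperature

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def weather_config():
    """A 12-year mid-latitude weather configuration (kept short so fits stay fast)."""
    return WeatherGenConfig(first_year=2000, last_year=2011, rng_seed=7)


@pytest.fixture(scope="session")
def temps(weather_config):
    return generate_temperature(weather_config)


@pytest.fixture(scope="session")
def latitude():
    return 40.0


@pytest.fixture(scope="session")
def noisefree_series(weather_config, temps, latitude):
    """Observations generated without noise from the photoperiod truth,
    together with the generating truth and the noise-free model dates."""
    truth = default_truth(observation_noise_sd=0.0, rng_seed=3)
    obs, clean = generate_phenology(truth, temps, latitude, weather_config.years)
    return obs, truth, clean


@pytest.fixture
def constant_temps():
    """Three years of constant 10 degC covering 1999-2002."""
    start = datetime.date(1999, 1, 1)
    n = (datetime.date(2002, 12, 31) - start).days + 1
    return DailyTemperatureSeries("CONST", start, np.full(n, 10.0))


def make_obs(values, years=None, station="S1"):
    years = years if years is not None else range(2000, 2000 + len(values))
    return PhenologyObservationSeries(
        station, "sp", Phenophase.FIRST_LEAF_UNFOLDING,
        {int(y): int(v) for y, v in zip(years, values)},
    )


@pytest.fixture
def obs_factory():
    return make_obs
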
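import numpy as np
import pytest

from vinewater import ClimateSpec, generate_synthetic_weather, load_site_config


@pytest.fixture(scope="session")
def climate_spec():
    return ClimateSpec()


@pytest.fixture(scope="session")
def weather_two_years(climate_spec):
    """Two years of synthetic daily weather, shared across tests."""
    return generate_synthetic_weather(climate_spec, 2, seed=20110101)


@pytest.fixture(scope="session")
def weather_one_year(weather_two_years):
    return weather_two_years[weather_two_years.index.year == 2001]


@pytest.fixture(scope="session")
def site_ef():
    return load_site_config("EF")


@pytest.fixture(scope="session")
def site_bu():
    return load_site_config("BU")


@pytest.fixture(scope="session")
def site_wi():
    return load_site_config("WI")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
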
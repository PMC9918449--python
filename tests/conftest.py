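import numpy as np
import pytest

import barleywl as bw
from barleywl.soil import generate_soil


WET_PARAMS = dict(
    mean_annual_rain=950.0,
    rain_season_phase=190.0,
    rain_season_amplitude=0.7,
    p_wet_given_wet=0.75,
    p_wet_given_dry=0.35,
    gamma_shape=0.9,
    temp_mean=11.0,
    temp_amplitude=6.0,
    temp_phase=20.0,
    radn_mean=14.0,
    radn_amplitude=8.0,
)
DRY_PARAMS = dict(
    mean_annual_rain=350.0,
    rain_season_phase=190.0,
    rain_season_amplitude=0.4,
    p_wet_given_wet=0.4,
    p_wet_given_dry=0.12,
    gamma_shape=0.8,
    temp_mean=13.0,
    temp_amplitude=7.0,
    temp_phase=20.0,
    radn_mean=16.0,
    radn_amplitude=8.0,
)


@pytest.fixture(scope="session")
def wet_weather():
    """Two years of winter-rainfall weather over a waterlogging-prone site."""
    return bw.generate_weather(
        bw.WeatherGenParams(**WET_PARAMS, seed=7), 2, 1990, latitude=-41.0
    )


@pytest.fixture(scope="session")
def dry_weather():
    return bw.generate_weather(
        bw.WeatherGenParams(**DRY_PARAMS, seed=7), 2, 1990, latitude=-35.0
    )


@pytest.fixture(scope="session")
def duplex_soil():
    return generate_soil("duplex_waterlogging_prone", seed=1)


@pytest.fixture(scope="session")
def drained_soil():
    return generate_soil("freely_drained", seed=1)


@pytest.fixture(scope="session")
def susceptible():
    return bw.Genotype("sus", "spring", 1.0, 1.0, 400.0, photo_floor=0.5)


@pytest.fixture(scope="session")
def tolerant():
    return bw.Genotype("tol", "spring", 1.0, 1.0, 400.0, photo_floor=1.0)


@pytest.fixture(scope="session")
def management():
    return bw.Management(sowing_doy=121)


@pytest.fixture(scope="session")
def wet_season_pair(wet_weather, duplex_soil, susceptible, tolerant, management):
    """(susceptible, tolerant, waterlogging-off) runs on the wet site."""
    sus = bw.simulate_season(wet_weather, duplex_soil, susceptible, management)
    tol = bw.simulate_season(wet_weather, duplex_soil, tolerant, management)
    off = bw.simulate_season(
        wet_weather, duplex_soil, susceptible, management, waterlogging_on=False
    )
    return sus, tol, off
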
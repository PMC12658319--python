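"""Shared fixtures: synthetic Boone-like seasons and default genotypes."""

import dataclasses
import datetime as dt

import pytest
from hypothesis import settings

import sorgsim as ss

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def weather_2021():
    return ss.generate_weather(2021, seed=101)


@pytest.fixture(scope="session")
def weather_2022_cold():
    return ss.generate_weather(2022, seed=102,
                               anomalies={"cold_october": True})


@pytest.fixture(scope="session")
def mgmt_2021():
    return ss.management_for_year(2021, 14.56)


@pytest.fixture(scope="session")
def default_g():
    return ss.default_genotype()


@pytest.fixture(scope="session")
def inputs_2021(weather_2021, mgmt_2021):
    return ss.prepare_season(weather_2021, mgmt_2021)


@pytest.fixture(scope="session")
def short_mgmt():
    """An 85-day season used by fast calibration tests."""
    return dataclasses.replace(ss.management_for_year(2021, 14.56),
                               harvest_date=dt.date(2021, 8, 20))


@pytest.fixture(scope="session")
def trace_2021(default_g, weather_2021, mgmt_2021):
    return ss.simulate_season(default_g, weather_2021, mgmt_2021)
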
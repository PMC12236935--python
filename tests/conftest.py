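import numpy as np
import pytest

from airburden.emissions import (
    ControlEfficiency,
    EmissionFactor,
    StackParameters,
    scenario_from_throughput,
)
from airburden.synth import generate_meteorology, generate_study_area


@pytest.fixture(scope="session")
def stack():
    return StackParameters(height=30.0, diameter=1.2, exit_velocity=15.0, exit_temperature=450.0)


@pytest.fixture(scope="session")
def factors():
    return [
        EmissionFactor("PM", 2.33),
        EmissionFactor("NOx", 1.78),
        EmissionFactor("SO2", 1.09),
        EmissionFactor("CO", 1.48),
    ]


@pytest.fixture(scope="session")
def controls():
    return [
        ControlEfficiency("PM", 0.984, ("FF", "ACI")),
        ControlEfficiency("NOx", 0.50),
        ControlEfficiency("SO2", 0.67, ("DSI",)),
        ControlEfficiency("CO", 0.0),
    ]


@pytest.fixture(scope="session")
def typical_scenario(factors, stack):
    return scenario_from_throughput(26_000.0, factors, None, stack, facility_id="mwi")


@pytest.fixture(scope="session")
def small_area():
    return generate_study_area(n_tracts=25, domain_radius=50_000.0, seed=7)


@pytest.fixture(scope="session")
def met_240():
    return generate_meteorology(240, prevailing_direction=270.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
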
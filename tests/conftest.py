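import pytest

from nepalsim.engine import (REFERENCE_FIXTURE_SEED, initialize_state,
                             run_simulation)
from nepalsim.params import ParameterSet, SimulationConfig
from nepalsim.scenarios import ScenarioSettings
from nepalsim.synthesis import generate_reference_fixture


@pytest.fixture(scope="session")
def reference():
    return generate_reference_fixture(REFERENCE_FIXTURE_SEED)


@pytest.fixture()
def params():
    return ParameterSet.defaults()


def make_config(**kw) -> SimulationConfig:
    kw.setdefault("simulation_length_days", 120)
    kw.setdefault("seed", 7)
    kw.setdefault("log_data", False)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def init_state():
    """A freshly initialised (day-0) village, shared read-mostly."""
    return initialize_state(make_config())


@pytest.fixture()
def fresh_state():
    """A private initialised village for tests that mutate it."""
    return initialize_state(make_config(seed=11))


@pytest.fixture(scope="session")
def short_run():
    """A 200-day logged run shared by log/summary/invariant tests."""
    cfg = make_config(simulation_length_days=200, seed=5, log_data=True)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def eq_scenario():
    return ScenarioSettings(earthquake=True, fertility_rate=2.1,
                            crop_variability="status_quo")
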
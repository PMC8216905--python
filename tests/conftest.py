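import datetime as dt

import pytest

from phenobee.scenario import (
    EXPERIMENT_END,
    EXPERIMENT_START,
    apply_warming_offset,
    build_photoperiod_schedule,
    build_weekly_means,
    expand_hourly,
    sinusoidal_climatology,
)
from phenobee.solar import SNASA, WURZBURG
from phenobee.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def climatology():
    return sinusoidal_climatology()


@pytest.fixture(scope="session")
def current_regime(climatology):
    return build_weekly_means(climatology)


@pytest.fixture(scope="session")
def future_regime(current_regime):
    return apply_warming_offset(current_regime, 4.0)


@pytest.fixture(scope="session")
def current_profile(current_regime):
    return expand_hourly(current_regime, EXPERIMENT_START, 22)


@pytest.fixture(scope="session")
def cep_schedule():
    return build_photoperiod_schedule("CEP", WURZBURG, (EXPERIMENT_START, EXPERIMENT_END))


@pytest.fixture(scope="session")
def nep_schedule():
    return build_photoperiod_schedule("NEP", SNASA, (EXPERIMENT_START, EXPERIMENT_END))


@pytest.fixture(scope="session")
def cd_schedule():
    return build_photoperiod_schedule("CD", None, (EXPERIMENT_START, EXPERIMENT_END))


@pytest.fixture(scope="session")
def study_bundle():
    """One full synthetic study, shared across tests (seed 1)."""
    return generate_study(SimulationConfig(seed=1))
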
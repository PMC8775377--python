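import numpy as np
import pytest

from glycosim import DaySchedule, MealEvent, ModelState, default_params
from glycosim.datasets import participant14_schedule, participant14_subject


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture
def rest_state(params):
    return ModelState.rest_equilibrium(params)


@pytest.fixture(scope="session")
def p14_schedule():
    return participant14_schedule()


@pytest.fixture(scope="session")
def p14_subject():
    return participant14_subject()


@pytest.fixture
def single_meal_schedule():
    return DaySchedule(meals=[MealEvent(t0=600.0, DGS=85.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
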
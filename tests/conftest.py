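import numpy as np
import pytest

from agrimoo.calibration import DEFAULT_CALIBRATION
from agrimoo.objectives import EconomicParams
from agrimoo.surrogate import ManagementPlan, WeatherSeries, load_soils


@pytest.fixture(scope="session")
def soils():
    return load_soils()


@pytest.fixture(scope="session")
def clay(soils):
    return soils["Clay"]


@pytest.fixture(scope="session")
def sandy_clay(soils):
    return soils["Sandy Clay"]


@pytest.fixture(scope="session")
def sandy_loam(soils):
    return soils["Sandy Loam"]


@pytest.fixture(scope="session")
def calib():
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def weather():
    return WeatherSeries.generate(42, n_seasons=9)


@pytest.fixture(scope="session")
def econ():
    return EconomicParams()


@pytest.fixture
def typical_plan():
    return ManagementPlan(
        n_rates=(0.0, 0.0, 60.0, 60.0, 60.0, 0.0, 0.0, 0.0, 0.0),
        fym_amount=1.0,
        fym_weeks_before_sowing=2,
    )


@pytest.fixture
def zero_plan():
    return ManagementPlan(n_rates=(0.0,) * 9)


def random_plan(rng: np.random.Generator) -> ManagementPlan:
    return ManagementPlan(
        n_rates=tuple(rng.uniform(0, 100, 9)),
        fym_amount=float(rng.uniform(0, 3)),
        fym_weeks_before_sowing=int(rng.integers(0, 4)),
    )
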
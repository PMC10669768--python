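import pytest
from hypothesis import HealthCheck, settings

from cageoxy import WaterConditions, case_study_scenario

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def wc15():
    """Seawater at 15 degC, 30 ppt, 1 atm (computed solubility)."""
    return WaterConditions(temperature=15.0, salinity=30.0)


@pytest.fixture
def scen10():
    return case_study_scenario(10.0)


@pytest.fixture
def scen15():
    return case_study_scenario(15.0)


@pytest.fixture
def scen20():
    return case_study_scenario(20.0)
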
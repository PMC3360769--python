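import pytest
from hypothesis import HealthCheck, settings

import mtaster as mt

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def generic():
    return mt.generic_cell()


@pytest.fixture(scope="session")
def generic_dc(generic):
    return mt.derived_constants(generic)


@pytest.fixture(scope="session")
def egg():
    return mt.EggScenario()
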
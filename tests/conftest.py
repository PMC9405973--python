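import pytest
from hypothesis import HealthCheck, settings

from itcthermo import EnergeticConstants, TitrationProtocol, load_constants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> EnergeticConstants:
    return EnergeticConstants()


@pytest.fixture(scope="session")
def bundle():
    return load_constants()


@pytest.fixture()
def protocol() -> TitrationProtocol:
    return TitrationProtocol()
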
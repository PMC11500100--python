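import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def domain():
    from fibresim.initialization import Domain
    return Domain(-400.0, 400.0, -400.0, 400.0, 30.0)
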
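import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smrdry import standard_fluids

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fluids():
    return standard_fluids()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
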
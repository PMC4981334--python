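import math

import pytest
from hypothesis import HealthCheck, settings

import graphgames as gg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

INF = math.inf


@pytest.fixture(scope="session")
def cycle6():
    return gg.make_ring(6, 2)


@pytest.fixture(scope="session")
def cycle10():
    return gg.make_ring(10, 2)


@pytest.fixture(scope="session")
def k4_complete():
    """K4: the only simple 3-regular graph on four vertices."""
    return gg.make_random_regular(4, 3, seed=0)


@pytest.fixture(scope="session")
def ring8k4():
    return gg.make_ring(8, 4)
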
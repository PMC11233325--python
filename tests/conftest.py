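import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishrhythm import LightSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    """The study's photoperiod: 14 h light, 10 h dark, recording from ZT1."""
    return LightSchedule()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240914)
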
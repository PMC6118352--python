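import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def region():
    from nanospat import StudyRegion

    return StudyRegion(1000.0, 1000.0)


@pytest.fixture
def short_radii():
    """A small grid for tests that do not need the full 1..240 nm range."""
    return np.arange(1.0, 61.0, 1.0)
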
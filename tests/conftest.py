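import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from rbscreen import ScanConfig
from rbscreen.synthesis import make_calibration_set

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> ScanConfig:
    return ScanConfig()


@pytest.fixture(scope="session")
def calibration_frame():
    """One full 5-subject calibration feature table (120 CF / 480 para rows)."""
    return make_calibration_set(n_subjects=5, seed=42)


@pytest.fixture(scope="session")
def fresh_calibration_frame():
    """A second, independently seeded table for held-out evaluation."""
    return make_calibration_set(n_subjects=5, seed=1042)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
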
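import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impactkin import SimulationConfig, analyze_pair, simulate_recording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def noiseless_recording(default_config):
    """Ground-truth pose and noiseless projected pair at defaults."""
    return simulate_recording(default_config)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_recording):
    pose, pair = noiseless_recording
    series, summary = analyze_pair(pair)
    return pose, series, summary


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
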
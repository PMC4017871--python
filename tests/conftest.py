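import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reachkin.simulate import PRESETS, simulate_trial

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_trial():
    """One noise-free healthy trial with ground truth."""
    cfg = PRESETS["healthy"]()
    cfg.noise_rms_mm = 0.0
    cfg.seed = 11
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def stroke_trial():
    """One noise-free stroke (forward-posture strategy) trial."""
    cfg = PRESETS["stroke-forward-posture"]()
    cfg.noise_rms_mm = 0.0
    cfg.seed = 11
    return simulate_trial(cfg, subject_id="P01", group="stroke")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
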
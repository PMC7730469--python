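import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

# deterministic property tests: same examples in every run
hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from gaitfatigue.io import CHANNELS
from gaitfatigue.simulate import GaitSimConfig, simulate_bout


NO_NOISE = {ch: 0.0 for ch in CHANNELS}


@pytest.fixture(scope="session")
def clean_bout():
    """Noiseless, jitter-free 1 Hz bout: every cycle is 50 identical samples."""
    cfg = GaitSimConfig(
        duration_min=3.0,
        cadence_hz=1.0,
        cadence_jitter_cv=0.0,
        noise_sd=dict(NO_NOISE),
        window_minutes=(1, 2, 3),
        seed=0,
    )
    return simulate_bout(cfg)


@pytest.fixture(scope="session")
def noisy_bout():
    """Default-noise, default-jitter 3-minute bout with known strikes."""
    cfg = GaitSimConfig(
        duration_min=3.0,
        cadence_hz=0.95,
        window_minutes=(1, 2, 3),
        seed=42,
    )
    return simulate_bout(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
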
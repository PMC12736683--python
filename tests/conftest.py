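import numpy as np
import pytest

from gaitevents import SyntheticConfig, generate_trial
from gaitevents.pipeline import RunConfig


@pytest.fixture(scope="session")
def zero_noise_config():
    """Noise-free 20 s trial with stride-to-stride variability retained."""
    return SyntheticConfig(trial_duration=20.0, noise_sd_grf=0.0,
                           noise_sd_marker=0.0, noise_sd_acc=0.0, rng_seed=3)


@pytest.fixture(scope="session")
def zero_noise_trial(zero_noise_config):
    return generate_trial(zero_noise_config)


@pytest.fixture(scope="session")
def noisy_trial():
    """20 s trial at the default (realistic) noise levels."""
    cfg = SyntheticConfig(trial_duration=20.0, rng_seed=5)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


def nearest_errors(detected, reference):
    """Signed error of the nearest detected event for each reference event."""
    det = np.asarray(detected, dtype=float)
    return np.array([det[np.argmin(np.abs(det - r))] - r for r in reference])
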
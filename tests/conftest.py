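import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import lumovar as lv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trial():
    """45-cycle trial with all noise sources at zero, plus its ground truth."""
    cfg = lv.TrialConfig(seed=7)
    return lv.generate_angle_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """Realistic trial: all three noise sources active."""
    cfg = lv.TrialConfig(
        seed=11, spatial_noise_sd=0.5, temporal_jitter_sd=0.08, process_noise_sd=0.02
    )
    return lv.generate_angle_trial(cfg)


@pytest.fixture(scope="session")
def default_run_config():
    return lv.RunConfig(expected_cycles=45)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every effect switched off."""
    cfg = lv.CohortConfig(
        seed=3, threat_effect=1.0, interaction_effect=1.0, threat_lde_shift=0.0,
        threat_amplitude_factor=1.0, threat_velocity_factor=1.0,
    )
    return lv.generate_cohort(cfg)


def smooth_random_angles(rng, n=600, rate=100.0, max_abs=45.0):
    """Band-limited random angle series bounded by ``max_abs`` degrees."""
    t = np.arange(n) / rate
    out = np.zeros((n, 3))
    for axis in range(3):
        x = sum(
            rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * rng.uniform(0.1, 1.5) * t + rng.uniform(0, 2 * np.pi))
            for _ in range(4)
        )
        out[:, axis] = max_abs * x / (np.abs(x).max() + 1e-12) * rng.uniform(0.5, 1.0)
    return out
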
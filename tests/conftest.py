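import pytest
from hypothesis import HealthCheck, settings

from calfface import CALF_FACE_10, HeadModelParams, simulate_trajectory

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schema():
    return CALF_FACE_10


@pytest.fixture(scope="session")
def small_sim():
    """A short noisy trajectory with ground truth, shared across tests."""
    params = HeadModelParams(n_frames=120, seed=42)
    observed, truth = simulate_trajectory(params)
    return params, observed, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, jitter-free trajectory: extracted traits are exact."""
    params = HeadModelParams(
        n_frames=60,
        seed=7,
        keypoint_noise_sd_px=0.0,
        angle_jitter_sd_deg=0.0,
        center_jitter_sd_px=0.0,
    )
    observed, truth = simulate_trajectory(params)
    return params, observed, truth
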
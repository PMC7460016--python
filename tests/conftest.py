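import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import motorkin as mk

settings.register_profile(
    "suite",
    max_examples=100,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profile() -> mk.SubjectProfile:
    return mk.SubjectProfile("S001", 25.0, "M", 175.0, 75.0, 300.0)


@pytest.fixture(scope="session")
def noise_free_script() -> mk.MotionScript:
    """Deterministic kinematics: no sway, no repetition-level jitter."""
    return dataclasses.replace(
        mk.MotionScript(),
        sway_amplitude_m=0.0,
        sst_angle_jitter_deg=0.0,
        fnt_jitter_sd_m=0.0,
        fnt_droop_sd_deg=0.0,
        cst_seat_jitter_m=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(profile, noise_free_script):
    """One noise-free protocol recording with its ground truth."""
    return mk.simulate_recording(
        profile, noise_free_script, mk.SensorModel().noiseless(), seed=11)


@pytest.fixture(scope="session")
def noisy_recording(profile):
    """Default-noise protocol recording with its ground truth."""
    return mk.simulate_recording(profile, seed=11)
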
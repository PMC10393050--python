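import numpy as np
import pytest

from specklesense.simulator import MotionModel, SimulationProtocol, simulate_recording


@pytest.fixture(scope="session")
def quiet_motion():
    """Motion model with every stochastic ingredient switched off."""
    return MotionModel(
        glucose_gain=0.0,
        pulse_amplitude=0.0,
        drift_step=0.0,
        boiling_rate=0.0,
        noise_std=0.0,
        field_off_coupling=0.0,
    )


@pytest.fixture(scope="session")
def short_protocol():
    """One-second 64 px field-on recording at the standard frame rate."""
    return SimulationProtocol(
        frame_size=64, fps=500.0, duration=1.0, glucose_level=150.0, seed=7
    )


@pytest.fixture(scope="session")
def clean_drive_video(short_protocol):
    """Field-on video whose only motion is the drive-frequency modulation."""
    motion = MotionModel(
        pulse_amplitude=0.0,
        drift_step=0.0,
        boiling_rate=0.0,
        noise_std=0.0,
    )
    return simulate_recording(short_protocol, motion)
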
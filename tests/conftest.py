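import numpy as np
import pytest

from pulsefusion.preprocess import PPGRecording
from pulsefusion.synth import PPGSimConfig, simulate_ppg


@pytest.fixture
def clean_60bpm_config() -> PPGSimConfig:
    """Noise-free 60-bpm beat train with well-separated systolic and
    diastolic components (closed-form per-beat extrema)."""
    return PPGSimConfig(
        duration=30.0,
        heart_rate=60.0,
        diastolic_ratio=0.4,
        systolic_diastolic_delay=0.3,
        systolic_width=0.08,
        diastolic_width=0.08,
    )


@pytest.fixture
def clean_60bpm_recording(clean_60bpm_config) -> PPGRecording:
    return simulate_ppg(clean_60bpm_config)


@pytest.fixture
def periodic_recording() -> PPGRecording:
    """Band-limited, exactly periodic signal whose period (1 s) is an
    integer number of samples at 25 Hz."""
    t = np.arange(750) / 25.0
    x = (
        np.sin(2 * np.pi * t)
        + 0.5 * np.sin(2 * np.pi * 2 * t + 0.4)
        + 0.2 * np.sin(2 * np.pi * 3 * t + 1.1)
    )
    return PPGRecording(samples=x, sampling_rate=25.0)
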
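import numpy as np
import pytest

from msalpha import StudyConfig
from msalpha.preprocess import GazeEpoch


@pytest.fixture
def clean_config():
    """Noise-free single-trial configuration for constructed-input tests."""
    return StudyConfig(
        n_participants=2,
        n_trials=1,
        drift_noise_sd=0.0,
        eye_noise_sd=0.0,
        blink_rate=0.0,
        eeg_noise_amplitude=0.0,
        calibration_noise_sd_deg=0.0,
        seed=0,
    )


@pytest.fixture
def small_config():
    """Small but fully noisy study for integration tests."""
    return StudyConfig(n_participants=4, n_trials=40, seed=11)


def make_epoch(position_pct, t0=-1000.0, cued_side="right", vertical=None, eyes=None):
    position_pct = np.asarray(position_pct, dtype=float)
    t = t0 + np.arange(position_pct.size, dtype=float)
    return GazeEpoch(
        time_ms=t,
        position_pct=position_pct,
        cued_side=cued_side,
        vertical_pct=vertical,
        eyes_pct=eyes,
    )


@pytest.fixture
def step_epoch():
    """Zero-noise epoch with a single instantaneous +5% step at 300 ms."""
    x = np.zeros(3000)
    t = -1000.0 + np.arange(3000.0)
    x[t >= 300.0] = 5.0
    return make_epoch(x)
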
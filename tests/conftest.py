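import numpy as np
import pytest

from nnskit.discrimination import AnalysisConfig
from nnskit.preprocess import ProcessedSignal
from nnskit.synthgen import DriftSpec, SynthConfig, _add_pulse, generate_assessment


@pytest.fixture
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture
def clean_record():
    """Noiseless, drift-free 3-minute synthetic assessment + ground truth."""
    cfg = SynthConfig(seed=7, noise_sd_cm_h2o=0.0, drift=DriftSpec.none())
    return generate_assessment(cfg)


def pulse_signal(events, duration_s=10.0, fs=100.0):
    """Baseline-corrected 100 Hz signal holding raised-cosine pulses.

    ``events`` is a list of (center_s, amplitude, half_width_s).
    """
    y = np.zeros(int(round(duration_s * fs)))
    for center, amp, half_w in events:
        _add_pulse(y, fs, center, amp, half_w)
    return ProcessedSignal.from_pressure(y, fs, assume_corrected=True)
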
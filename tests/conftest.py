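import numpy as np
import pytest

from csfdyn.datatypes import ICPTrace
from csfdyn.synthetic import ScenarioParams, gen_icp_trace


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free reference animal: baseline 4 mmHg, ventilation 1.3 Hz
    at 1 mmHg, cardiac 4 Hz at 0.06 mmHg (MWA truth 0.12)."""
    return ScenarioParams(baseline_icp=4.0, vent_amp=1.0, vent_freq=1.3,
                          cardiac_amp=0.06, cardiac_freq=4.0,
                          icp_noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_trace(clean_params):
    """300 s noise-free 1 kHz trace shared across waveform tests."""
    return gen_icp_trace(clean_params, duration=300.0)


def make_tone(freq, amp=1.0, fs=1000.0, duration=30.0, offset=0.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return ICPTrace(time=t, pressure=offset + amp * np.sin(2 * np.pi * freq * t + phase),
                    sampling_rate=fs)


def fit_sinusoid(time, x, freq):
    """Least-squares amplitude of a sinusoid at ``freq`` plus DC."""
    design = np.column_stack([np.sin(2 * np.pi * freq * time),
                              np.cos(2 * np.pi * freq * time),
                              np.ones_like(time)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[0], coef[1])), float(coef[2])
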
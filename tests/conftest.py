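import logging

import numpy as np
import pytest

import photosurge as ps

logging.getLogger("photosurge").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def proestrus_run():
    """One synthetic proestrous recording run through the full pipeline."""
    raw, truth = ps.generate_recording("proestrus", seed=7)
    result = ps.run_pipeline(raw)
    return raw, truth, result


def make_trace(values, dt=4.0, clock_start="11:00"):
    """CalciumTrace on a uniform grid with default clock anchoring."""
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) * dt
    return ps.CalciumTrace(times, values, {"clock_start": clock_start,
                                           "lights_off": "19:00"})


def bump_train(duration_s, events, dt=4.0, noise_sd=0.0, rng=None):
    """Raised-cosine bump trace: events = [(onset_s, duration_s, amp), ...]."""
    t = np.arange(0.0, duration_s, dt)
    y = np.zeros_like(t)
    for onset, dur, amp in events:
        phase = (t - onset) / dur
        m = (phase >= 0) & (phase <= 1)
        y[m] += amp * 0.5 * (1 - np.cos(2 * np.pi * phase[m]))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(t))
    return t, y
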
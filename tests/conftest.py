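import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from cardiobeat.synth_signals import (  # noqa: E402
    BeatScheduleParams,
    McgWaveformParams,
    generate_beat_schedule,
    render_mcg_trace,
)


@pytest.fixture
def regular_schedule():
    """Deterministic 60-bpm schedule: beats at 0, 1, ..., 9 s."""
    params = BeatScheduleParams(
        base_rate=60.0, rate_jitter_cv=0.0, pause_rate=0.0, duration=10.0
    )
    return generate_beat_schedule(params)


@pytest.fixture
def noisy_trace():
    """60 s of jittered 60-bpm beating, 2% amplitude noise, drift on."""
    params = BeatScheduleParams(
        base_rate=60.0, rate_jitter_cv=0.05, pause_rate=0.0, duration=60.0, seed=7
    )
    beats, gt = generate_beat_schedule(params)
    wf = McgWaveformParams(noise_sd=2.0, drift_amplitude=5.0, drift_period=20.0)
    seg, _ = render_mcg_trace(beats, wf, seed=11, duration=61.0)
    return seg, beats, wf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
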
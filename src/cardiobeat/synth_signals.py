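"""Synthetic cardiomyocyte recordings with known ground truth.

Generates the three signal types of an in vitro drug-response experiment:

* mechanocardiogram (MCG) force traces — biphasic contraction events (R peak,
  S undershoot) on a noisy, slowly drifting baseline, emulating an AFM
  cantilever pressed on a beating cardiomyocyte cluster;
* multielectrode-array (MEA) field potentials — short biphasic spikes per beat
  on several channels with channel-specific latencies, some channels unusable;
* calcium line-scan fluorescence — periodic transients (fast rise, exponential
  decay) with interspersed low-amplitude diastolic sparks at 100 Hz line rate.

All generators share one beat schedule built by :func:`generate_beat_schedule`,
which models spontaneous beating with beat-to-beat jitter, rare long pauses
(the "stochastic" arrhythmia phenotype: an extreme inter-beat interval), and
optional tachy-brady alternation (square-wave rate modulation).  Every
stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GroundTruth, RecordingSegment
from .errors import ParameterError

__all__ = [
    "BeatScheduleParams",
    "DrugResponseParams",
    "McgWaveformParams",
    "MeaSpikeParams",
    "CalciumSimParams",
    "generate_beat_schedule",
    "render_mcg_trace",
    "render_mea_recording",
    "render_calcium_linescan",
    "chronotropic_multiplier",
]

# Fractions of the contraction event width spent in upstroke / decline to the
# S trough / recovery to baseline.  The R peak sits exactly at the scheduled
# beat time.
_UPSTROKE_FRAC = 0.2
_DOWNSTROKE_FRAC = 0.35


@dataclass
class BeatScheduleParams:
    """Spontaneous-beating schedule parameters.

    base_rate : beats per minute (spontaneous rate; 10-120 bpm is the
        physiological range covered by the models emulated here).
    rate_jitter_cv : coefficient of variation of inter-beat intervals.
    pause_rate : expected extreme-pause events per 1000 beats.  Pauses are
        injected by lengthening a randomly chosen inter-beat interval, so each
        maps one-to-one to an extreme R-R interval in the ground truth.
    pause_duration_range : (min, max) pause length in seconds; must exceed the
        longest ordinary interval so an injected pause is unambiguous.
    tachy_brady_* : square-wave rate modulation — the rate alternates between
        ``base_rate * ratio`` and ``base_rate / ratio`` every half period.
    """

    base_rate: float = 40.0
    rate_jitter_cv: float = 0.05
    pause_rate: float = 0.0
    pause_duration_range: tuple[float, float] = (4.0, 6.0)
    tachy_brady_enabled: bool = False
    tachy_brady_period: float = 10.0
    tachy_brady_rate_ratio: float = 1.5
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ParameterError("base_rate must be positive")
        if self.rate_jitter_cv < 0:
            raise ParameterError("rate_jitter_cv must be >= 0")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.pause_rate < 0:
            raise ParameterError("pause_rate must be >= 0")
        lo, hi = self.pause_duration_range
        if self.pause_rate > 0:
            if not 0 < lo <= hi:
                raise ParameterError("pause_duration_range must satisfy 0 < min <= max")
            slowest_ibi = 60.0 / self.base_rate
            if self.tachy_brady_enabled:
                slowest_ibi *= self.tachy_brady_rate_ratio
            if lo <= slowest_ibi:
                raise ParameterError(
                    "minimum pause duration must exceed the longest ordinary "
                    f"inter-beat interval ({slowest_ibi:.3g} s)"
                )
        if self.tachy_brady_enabled:
            if self.tachy_brady_period <= 0 or self.tachy_brady_rate_ratio <= 0:
                raise ParameterError("tachy-brady period and ratio must be positive")


@dataclass
class DrugResponseParams:
    """Phenomenological drug effect across a concentration ladder.

    chronotropy_slope : relative beat-rate increase per log10(concentration)
        decade (relative to the lowest concentration of the ladder), the
        concentration-dependent ("deterministic") effect.
    inotropy_profile : relative force multiplier per concentration; may be
        non-monotone (inotropy saturating or reversing at high dose).
    arrhythmia_rate : extreme-pause rate per 1000 beats, shared across all
        concentrations — the concentration-independent ("stochastic") effect.
    spark_rate_profile : calcium sparks per second of diastole, per
        concentration (None -> a flat default).
    """

    concentrations: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
    chronotropy_slope: float = 0.1
    inotropy_profile: tuple[float, ...] = (1.25, 1.10, 1.20, 1.05)
    arrhythmia_rate: float = 20.0
    spark_rate_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ParameterError("concentrations must be strictly positive")
        if len(self.inotropy_profile) != len(self.concentrations):
            raise ParameterError("inotropy_profile length must match concentrations")
        if any(m <= 0 for m in self.inotropy_profile):
            raise ParameterError("inotropy multipliers must be positive")
        if self.arrhythmia_rate < 0:
            raise ParameterError("arrhythmia_rate must be >= 0")


def chronotropic_multiplier(params: DrugResponseParams, concentration: float) -> float:
    """Relative beat-rate multiplier at ``concentration``.

    Linear in log10(concentration), anchored at 1.0 for the lowest
    concentration of the ladder, so a regression of relative beat rate on
    log10(concentration) recovers ``chronotropy_slope`` directly.
    """
    c0 = min(params.concentrations)
    return 1.0 + params.chronotropy_slope * np.log10(concentration / c0)


@dataclass
class McgWaveformParams:
    """Shape of one MCG contraction event and of the background.

    The event is an asymmetric biphasic template: fast upstroke to the R peak
    (height ``contraction_amplitude``), decline to an S trough at
    ``-relaxation_depth_fraction * amplitude``, smooth return to baseline —
    all within ``event_width`` seconds.  The R-S span is therefore
    ``amplitude * (1 + relaxation_depth_fraction)``.
    """

    contraction_amplitude: float = 100.0   # nN
    relaxation_depth_fraction: float = 0.2
    event_width: float = 0.5               # s
    noise_sd: float = 0.0                  # nN
    drift_amplitude: float = 0.0           # nN
    drift_period: float = 30.0             # s
    sampling_rate: float = 1000.0          # Hz

    def __post_init__(self) -> None:
        if self.contraction_amplitude <= 0:
            raise ParameterError("contraction_amplitude must be positive")
        if not 0 <= self.relaxation_depth_fraction < 1:
            raise ParameterError("relaxation_depth_fraction must be in [0, 1)")
        if self.event_width <= 0:
            raise ParameterError("event_width must be positive")
        if self.sampling_rate < 50:
            raise ParameterError("sampling_rate must be >= 50 Hz")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ParameterError("noise/drift amplitudes must be >= 0")

    @property
    def rs_span(self) -> float:
        """The R-S amplitude a noiseless event produces."""
        return self.contraction_amplitude * (1.0 + self.relaxation_depth_fraction)


@dataclass
class MeaSpikeParams:
    """Field-potential spike shape for the MEA renderer."""

    spike_amplitude: float = 300.0   # uV
    spike_width: float = 0.004       # s, full biphasic width
    noise_sd: float = 10.0           # uV
    max_latency: float = 0.008       # s, channel-specific conduction latency
    sampling_rate: float = 10000.0   # Hz

    def __post_init__(self) -> None:
        if self.spike_amplitude <= 0 or self.spike_width <= 0:
            raise ParameterError("spike amplitude and width must be positive")
        if not 0 <= self.max_latency < 0.010:
            raise ParameterError("channel latency must be < 10 ms")


@dataclass
class CalciumSimParams:
    """Calcium line-scan simulation parameters (dF/F0 units).

    rise_time is the 10%->100% rise duration of a transient (the generator
    uses a linear ramp of total length rise_time/0.9 so the measured
    time-to-peak, onset at the 10% crossing, equals rise_time).  Decay is a
    pure exponential with time constant decay_tau, so the peak->10% decay
    time is decay_tau * ln(10).  Sparks are low-amplitude Gaussian bumps
    placed uniformly at random in diastolic intervals.
    """

    transient_amplitude: float = 2.0       # dF/F0
    rise_time: float = 0.05                # s (10% -> 100%)
    decay_tau: float = 0.2                 # s
    spark_rate: float = 0.0                # events / s of diastole
    spark_amplitude_fraction: float = 0.3
    spark_width: float = 0.08              # s FWHM
    line_rate: float = 100.0               # Hz
    noise_sd: float = 0.02                 # dF/F0

    def __post_init__(self) -> None:
        if self.transient_amplitude <= 0 or self.rise_time <= 0:
            raise ParameterError("transient amplitude and rise time must be positive")
        if self.decay_tau <= 0:
            raise ParameterError("decay_tau must be positive")
        if not 0 < self.spark_amplitude_fraction < 1:
            raise ParameterError(
                "spark_amplitude_fraction must be in (0, 1): sparks are sub-transient"
            )
        if self.spark_rate < 0 or self.noise_sd < 0:
            raise ParameterError("rates and noise must be >= 0")


# ---------------------------------------------------------------------------
# beat schedule


def _instantaneous_rate(params: BeatScheduleParams, t: float) -> float:
    if not params.tachy_brady_enabled:
        return params.base_rate
    phase = t % params.tachy_brady_period
    if phase < params.tachy_brady_period / 2.0:
        return params.base_rate * params.tachy_brady_rate_ratio
    return params.base_rate / params.tachy_brady_rate_ratio


def generate_beat_schedule(
    params: BeatScheduleParams,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate beat times for one recording.

    Returns the beat times (seconds, first beat at 0) and a
    :class:`GroundTruth` whose ``pause_indices`` list every injected extreme
    interval.  The number of injected pauses is Poisson with mean
    ``pause_rate * n_beats / 1000``.
    """
    rng = np.random.default_rng(params.seed)
    base_ibi = 60.0 / params.base_rate

    if params.tachy_brady_enabled:
        # rate depends on current time -> sequential construction
        times = [0.0]
        t = 0.0
        while True:
            ibi = 60.0 / _instantaneous_rate(params, t)
            if params.rate_jitter_cv > 0:
                ibi *= max(1.0 + params.rate_jitter_cv * rng.standard_normal(), 0.1)
            t += ibi
            if t >= params.duration:
                break
            times.append(t)
        beat_times = np.array(times)
    else:
        n_draw = int(np.ceil(params.duration / base_ibi * 1.5)) + 50
        ibis = np.full(n_draw, base_ibi)
        if params.rate_jitter_cv > 0:
            ibis = ibis * np.maximum(
                1.0 + params.rate_jitter_cv * rng.standard_normal(n_draw), 0.1
            )
        t = np.concatenate([[0.0], np.cumsum(ibis)])
        beat_times = t[t < params.duration]

    intervals = np.diff(beat_times)
    pause_idx = np.empty(0, dtype=int)
    if params.pause_rate > 0 and intervals.size > 0:
        n_beats = beat_times.size
        n_pauses = int(rng.poisson(params.pause_rate * n_beats / 1000.0))
        n_pauses = min(n_pauses, intervals.size)
        if n_pauses > 0:
            pause_idx = np.sort(
                rng.choice(intervals.size, size=n_pauses, replace=False)
            )
            lo, hi = params.pause_duration_range
            intervals[pause_idx] = rng.uniform(lo, hi, n_pauses)
            beat_times = np.concatenate([[0.0], np.cumsum(intervals)])

    realized = max(params.duration, float(beat_times[-1]) + base_ibi)
    gt = GroundTruth(
        beat_times=beat_times, pause_indices=pause_idx, duration=realized
    )
    return beat_times, gt


# ---------------------------------------------------------------------------
# MCG renderer


def _mcg_template(u: np.ndarray, depth: float) -> np.ndarray:
    """Contraction event shape on normalized time u in [-a, 1-a] (peak at 0).

    Unit R-peak height; S trough at -depth.
    """
    a, b = _UPSTROKE_FRAC, _DOWNSTROKE_FRAC
    y = np.zeros_like(u)
    m = (u >= -a) & (u < 0)
    y[m] = np.sin(0.5 * np.pi * (u[m] + a) / a)
    m = (u >= 0) & (u < b)
    y[m] = 0.5 * (1 + depth) * np.cos(np.pi * u[m] / b) + 0.5 * (1 - depth)
    m = (u >= b) & (u <= 1 - a)
    y[m] = -depth * 0.5 * (1 + np.cos(np.pi * (u[m] - b) / (1 - a - b)))
    return y


def render_mcg_trace(
    beat_times: np.ndarray,
    waveform: McgWaveformParams,
    seed: int = 0,
    amplitudes: np.ndarray | None = None,
    duration: float | None = None,
    stabilization_s: float = 0.0,
    label: str = "",
) -> tuple[RecordingSegment, GroundTruth]:
    """Render an MCG force trace from a beat schedule.

    Each beat contributes one biphasic contraction event whose R peak sits at
    the scheduled time.  Gaussian noise and a sinusoidal baseline drift are
    added on top.  Returns the trace and a ground truth carrying the schedule
    and per-beat amplitudes.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ParameterError("beat times must be strictly increasing")
    if beat_times.size > 1 and np.min(np.diff(beat_times)) <= waveform.event_width:
        raise ParameterError("contraction events overlap at this event_width")

    if duration is None:
        duration = (beat_times[-1] + waveform.event_width if beat_times.size else 1.0)
    fs = waveform.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if amplitudes is None:
        amplitudes = np.full(beat_times.size, waveform.contraction_amplitude)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != beat_times.shape:
        raise ParameterError("one amplitude per beat required")

    x = np.zeros(n)
    w = waveform.event_width
    for t0, amp in zip(beat_times, amplitudes):
        lo = int(np.floor((t0 - _UPSTROKE_FRAC * w) * fs))
        hi = int(np.ceil((t0 + (1 - _UPSTROKE_FRAC) * w) * fs)) + 1
        lo, hi = max(lo, 0), min(hi, n)
        if hi <= lo:
            continue
        u = (t[lo:hi] - t0) / w
        x[lo:hi] += amp * _mcg_template(u, waveform.relaxation_depth_fraction)

    rng = np.random.default_rng(seed)
    if waveform.drift_amplitude > 0:
        x += waveform.drift_amplitude * np.sin(2 * np.pi * t / waveform.drift_period)
    if waveform.noise_sd > 0:
        x += rng.normal(0.0, waveform.noise_sd, n)

    seg = RecordingSegment(
        t, x, fs, units="nN", label=label, stabilization_s=stabilization_s
    )
    gt = GroundTruth(beat_times=beat_times, amplitudes=amplitudes, duration=duration)
    return seg, gt


# ---------------------------------------------------------------------------
# MEA renderer


def _mea_spike_template(u: np.ndarray) -> np.ndarray:
    """Biphasic field-potential spike on u in [0, 1]: positive then negative lobe."""
    y = np.zeros_like(u)
    m = (u >= 0) & (u < 0.5)
    y[m] = np.sin(2 * np.pi * u[m])
    m = (u >= 0.5) & (u <= 1)
    y[m] = 0.7 * np.sin(2 * np.pi * u[m])
    return y


def render_mea_recording(
    beat_times: np.ndarray,
    n_channels: int = 6,
    n_bad_channels: int = 0,
    spike: MeaSpikeParams | None = None,
    seed: int = 0,
    duration: float | None = None,
    stabilization_s: float = 0.0,
    label: str = "",
) -> tuple[RecordingSegment, GroundTruth]:
    """Render a multichannel field-potential recording.

    Good channels carry one biphasic spike per beat with a fixed
    channel-specific latency (< 10 ms); bad channels carry noise only.  The
    ground truth marks which channels are bad.
    """
    if n_channels < 3:
        raise ParameterError("MEA pipeline requires at least 3 channels")
    if n_bad_channels >= n_channels:
        raise ParameterError("n_bad_channels must be < n_channels")
    spike = spike or MeaSpikeParams()
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ParameterError("beat times must be strictly increasing")

    if duration is None:
        duration = (beat_times[-1] + 0.1 if beat_times.size else 1.0)
    fs = spike.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    rng = np.random.default_rng(seed)
    bad = np.sort(rng.choice(n_channels, size=n_bad_channels, replace=False))
    latencies = rng.uniform(0.0, spike.max_latency, n_channels)

    x = np.zeros((n, n_channels))
    w = spike.spike_width
    for ch in range(n_channels):
        if ch in bad:
            continue
        for t0 in beat_times + latencies[ch]:
            lo = int(np.floor(t0 * fs))
            hi = int(np.ceil((t0 + w) * fs)) + 1
            lo, hi = max(lo, 0), min(hi, n)
            if hi <= lo:
                continue
            u = (t[lo:hi] - t0) / w
            x[lo:hi, ch] += spike.spike_amplitude * _mea_spike_template(u)
    if spike.noise_sd > 0:
        x += rng.normal(0.0, spike.noise_sd, x.shape)

    seg = RecordingSegment(
        t, x, fs, units="uV", label=label, stabilization_s=stabilization_s
    )
    gt = GroundTruth(beat_times=beat_times, bad_channels=bad, duration=duration)
    return seg, gt


# ---------------------------------------------------------------------------
# calcium renderer


def transient_template(
    t: np.ndarray, t_peak: float, params: CalciumSimParams
) -> np.ndarray:
    """One calcium transient (dF/F0): linear rise to the peak, exponential decay."""
    a = params.transient_amplitude
    t_full = params.rise_time / 0.9  # full 0->100% ramp so 10->100% == rise_time
    y = np.zeros_like(t)
    m = (t >= t_peak - t_full) & (t <= t_peak)
    y[m] = a * (t[m] - (t_peak - t_full)) / t_full
    m = t > t_peak
    y[m] = a * np.exp(-(t[m] - t_peak) / params.decay_tau)
    return y


def _transient_spans(
    transient_times: np.ndarray, params: CalciumSimParams
) -> list[tuple[float, float]]:
    t_full = params.rise_time / 0.9
    return [
        (tp - t_full, tp + 5.0 * params.decay_tau) for tp in transient_times
    ]


def render_calcium_linescan(
    transient_times: np.ndarray,
    params: CalciumSimParams,
    seed: int = 0,
    duration: float | None = None,
    n_positions: int = 0,
    label: str = "",
) -> tuple[RecordingSegment, GroundTruth]:
    """Render a calcium line-scan fluorescence trace (dF/F0 model -> raw a.u.).

    ``transient_times`` are the peak times of the main calcium waves.  Sparks
    are inserted uniformly at random in the diastolic intervals (outside every
    transient's rise-to-decay span) at ``params.spark_rate`` per second of
    diastole.  The returned trace is raw fluorescence ``F0 * (1 + dF/F0)``
    with F0 = 100 a.u., so the dF/F0 normalization step is exercised
    downstream.  With ``n_positions > 0`` a 2-D kymograph is returned instead:
    the same profile replicated over positions with independent spatial noise.
    """
    transient_times = np.sort(np.asarray(transient_times, dtype=float))
    if transient_times.size > 1:
        min_gap = params.rise_time + 3.0 * params.decay_tau
        if np.min(np.diff(transient_times)) <= min_gap:
            raise ParameterError(
                f"transient spacing must exceed rise_time + 3*decay_tau ({min_gap:.3g} s)"
            )
    if duration is None:
        duration = (
            transient_times[-1] + 6 * params.decay_tau if transient_times.size else 1.0
        )
    fs = params.line_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    dff = np.zeros(n)
    for tp in transient_times:
        dff += transient_template(t, tp, params)

    rng = np.random.default_rng(seed)
    spark_times = np.empty(0)
    if params.spark_rate > 0:
        spans = _transient_spans(transient_times, params)
        # diastolic windows, kept clear of the trace edges and span edges by
        # one spark width so detection is not censored
        pad = params.spark_width
        edges = [0.0] + [e for s in spans for e in s] + [duration]
        windows = []
        for lo, hi in zip(edges[0::2], edges[1::2]):
            lo, hi = lo + pad, hi - pad
            if hi > lo:
                windows.append((lo, hi))
        total = sum(hi - lo for lo, hi in windows)
        if total > 0:
            n_sparks = int(rng.poisson(params.spark_rate * total))
            u = rng.uniform(0.0, total, n_sparks)
            starts = np.cumsum([0.0] + [hi - lo for lo, hi in windows])
            raw_times = np.sort(
                [windows[np.searchsorted(starts, ui, "right") - 1][0]
                 + (ui - starts[np.searchsorted(starts, ui, "right") - 1])
                 for ui in u]
            )
            # hard-core thinning: release sites are refractory, so sparks
            # closer than twice their width are one physical event — keep the
            # earlier one so ground truth lists resolvable events only
            kept: list[float] = []
            for ts in raw_times:
                if not kept or ts - kept[-1] >= 2.0 * params.spark_width:
                    kept.append(ts)
            spark_times = np.asarray(kept)
            sigma = params.spark_width / (2 * np.sqrt(2 * np.log(2)))
            amp = params.spark_amplitude_fraction * params.transient_amplitude
            for ts in spark_times:
                m = np.abs(t - ts) < 4 * sigma
                dff[m] += amp * np.exp(-0.5 * ((t[m] - ts) / sigma) ** 2)
            spark_times = np.asarray(spark_times)

    f0 = 100.0
    if n_positions > 0:
        raw = f0 * (1.0 + dff[:, None])
        raw = raw + rng.normal(0.0, f0 * params.noise_sd, (n, n_positions))
        units = "au"
    else:
        raw = f0 * (1.0 + dff)
        if params.noise_sd > 0:
            raw = raw + rng.normal(0.0, f0 * params.noise_sd, n)
        units = "au"

    seg = RecordingSegment(t, raw, fs, units=units, label=label)
    gt = GroundTruth(
        spark_times=spark_times,
        transient_times=transient_times,
        duration=duration,
    )
    return seg, gt
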
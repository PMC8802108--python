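"""Core containers shared across the pipeline.

A recording is represented by :class:`RecordingSegment` (uniformly sampled
time + signal, single- or multi-channel).  Beat analysis produces
:class:`BeatEvent` / :class:`BeatSeries`; simulators attach a
:class:`GroundTruth` describing what was injected so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NormalizationError

#: Allowed relative deviation of the sample spacing from uniformity.
UNIFORMITY_RTOL = 1e-6


@dataclass
class RecordingSegment:
    """One uniformly sampled recording segment.

    Parameters
    ----------
    time : ndarray, seconds, strictly increasing and uniform.
    signal : ndarray, shape ``(n,)`` for single channel or ``(n, n_channels)``.
    sampling_rate : Hz.
    units : physical units of ``signal`` ("nN" for force, "uV" for field
        potential, "au" for raw fluorescence).
    label : free-text condition label (e.g. "baseline", "A 10 uM").
    stabilization_s : leading stretch that is recorded but excluded from all
        metrics, mirroring the stabilization phase of a drug-response protocol.
    """

    time: np.ndarray
    signal: np.ndarray
    sampling_rate: float
    units: str = "au"
    label: str = ""
    stabilization_s: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise InputError("time must be a 1-D array with at least 2 samples")
        if self.signal.shape[0] != self.time.shape[0]:
            raise InputError("signal and time lengths differ")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise InputError("time must be strictly increasing")
        step = 1.0 / self.sampling_rate
        if np.any(np.abs(dt - step) > UNIFORMITY_RTOL * max(step, 1.0) + 1e-12):
            raise InputError("non-uniform sampling (does not match sampling_rate)")

    @property
    def n_channels(self) -> int:
        return 1 if self.signal.ndim == 1 else self.signal.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel(self, i: int) -> "RecordingSegment":
        """Extract one channel of a multichannel segment."""
        if self.signal.ndim == 1:
            if i != 0:
                raise InputError("single-channel segment")
            return self
        return RecordingSegment(
            self.time, self.signal[:, i], self.sampling_rate,
            units=self.units, label=f"{self.label}/ch{i}",
            stabilization_s=self.stabilization_s,
        )

    def measurement(self) -> "RecordingSegment":
        """The segment with the stabilization phase trimmed off."""
        if self.stabilization_s <= 0:
            return self
        keep = self.time >= self.time[0] + self.stabilization_s
        if keep.sum() < 2:
            raise InputError("stabilization phase longer than the recording")
        return RecordingSegment(
            self.time[keep], self.signal[keep], self.sampling_rate,
            units=self.units, label=self.label, stabilization_s=0.0,
        )


@dataclass(frozen=True)
class BeatEvent:
    """One contractile/electrical event: R peak and the following S trough."""

    r_time: float
    r_deflection: float
    s_time: float
    s_deflection: float

    def __post_init__(self) -> None:
        if not self.s_time > self.r_time:
            raise InputError("S trough must follow the R peak")
        if not self.r_deflection > self.s_deflection:
            raise InputError("R deflection must exceed S deflection")

    @property
    def rs_amplitude(self) -> float:
        return self.r_deflection - self.s_deflection


class BeatSeries:
    """Ordered beat events from one recording segment with derived metrics.

    ``rr_intervals`` has length ``n_events - 1`` (time between successive R
    peaks); ``rs_amplitudes`` has length ``n_events``.  ``beat_rate`` is
    defined from the mean R-R interval (see :func:`beat_detection.beat_rate`).
    """

    def __init__(self, events: list[BeatEvent], duration: float | None = None):
        self.events = list(events)
        self.duration = duration
        r = np.array([e.r_time for e in self.events])
        if np.any(np.diff(r) <= 0):
            raise InputError("beat events must be strictly ordered in time")
        self.rr_intervals: np.ndarray = np.diff(r)
        self.rs_amplitudes: np.ndarray = np.array(
            [e.rs_amplitude for e in self.events]
        )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def r_times(self) -> np.ndarray:
        return np.array([e.r_time for e in self.events])

    @property
    def beat_rate(self) -> float | None:
        """Beats per minute from the mean R-R interval; None if < 2 events."""
        if len(self.rr_intervals) == 0:
            return None
        return 60.0 / float(np.mean(self.rr_intervals))


@dataclass
class GroundTruth:
    """What a simulator injected, for recovery scoring downstream.

    ``pause_indices`` are indices into the inter-beat-interval sequence
    (interval ``i`` separates beats ``i`` and ``i+1``): each injected pause
    maps one-to-one to an extreme R-R interval.
    """

    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray | None = None
    pause_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    spark_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    transient_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bad_channels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    duration: float = 0.0

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(np.asarray(self.beat_times))


@dataclass(frozen=True)
class RelativeResponse:
    """A treatment metric normalized to its own baseline (and optionally to a
    control-group mean ratio, the second-stage normalization used for
    dose-response scatterplots)."""

    metric: str
    treatment_mean: float
    baseline_mean: float
    control_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.baseline_mean > 0:
            raise NormalizationError(
                f"baseline mean for {self.metric!r} must be positive"
            )
        if not self.control_ratio > 0:
            raise NormalizationError("control-group ratio must be positive")

    @property
    def ratio(self) -> float:
        """treatment / baseline."""
        return self.treatment_mean / self.baseline_mean

    @property
    def control_normalized(self) -> float:
        """Ratio further divided by the control-group mean ratio."""
        return self.ratio / self.control_ratio
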
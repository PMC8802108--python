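"""R/S peak detection and contraction metrics for MCG force traces.

An MCG records the force a beating cardiomyocyte cluster exerts on an AFM
cantilever.  Each contractile event shows a sharp positive R peak followed by
an S trough; the R-S span is the contraction force (nN), R-R intervals give
the rhythm, and 60 / mean(R-R) is the beat rate (bpm).

Detection strategy: R peaks are local maxima exceeding an adaptive prominence
threshold — the larger of an absolute floor, a multiple of the robust noise SD
(MAD-based), and a fraction of the segment's robust amplitude range — and
separated by at least a refractory period.  The paired S trough is the signal
minimum between the R peak and the next one (or the segment end).  Plateau
ties resolve to the earliest sample.  The detector is deterministic for a
fixed input and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .core import BeatEvent, BeatSeries, RecordingSegment, RelativeResponse
from .errors import NormalizationError, UndefinedMetricError

__all__ = [
    "DetectorConfig",
    "MCG_DETECTOR",
    "MEA_DETECTOR",
    "detect_beats",
    "beat_rate",
    "contraction_force",
    "normalize_to_baseline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detector configuration.

    prominence_floor : absolute minimum prominence, in signal units.
    prominence_fraction : fraction of the robust amplitude range
        (99.5th percentile minus median) an R peak must reach.
    noise_multiple : minimum prominence in robust-noise-SD units
        (SD = 1.4826 * MAD), the floor that rejects baseline noise.
    refractory_s : minimum separation between events.  Defaults: 0.25 s for
        MCG (human PSC-derived cardiomyocytes), 0.10 s for MEA (murine HL-1,
        which beats faster) — below the fastest physiological rate of each
        model.
    detrend : subtract a moving-median baseline (window = detrend_periods x
        the median beat period estimated in a first pass) before detection.
    fit_window_s : half-width of the local parabola fit used to read R/S
        deflections; the fit averages sampling noise so amplitudes are not
        biased by extreme-value selection on noisy samples.  Set to 0 to read
        raw sample values.
    """

    prominence_floor: float = 0.0
    prominence_fraction: float = 0.25
    noise_multiple: float = 5.0
    range_percentile: float = 99.5
    refractory_s: float = 0.25
    detrend: bool = False
    detrend_periods: float = 3.0
    fit_window_s: float = 0.012


MCG_DETECTOR = DetectorConfig(refractory_s=0.25)
# MEA field potentials: spikes are a few ms wide and occupy < 1% of samples,
# so the amplitude range must use the full maximum, and at 10 kHz the extreme
# prominence of pure noise over a refractory window reaches ~9 noise SDs, so
# the noise floor multiple is raised accordingly.
MEA_DETECTOR = DetectorConfig(
    refractory_s=0.10,
    fit_window_s=0.001,
    noise_multiple=12.0,
    prominence_fraction=0.4,
    range_percentile=100.0,
)


def _prominence_threshold(x: np.ndarray, config: DetectorConfig) -> float:
    med = np.median(x)
    mad_sd = 1.4826 * np.median(np.abs(x - med))
    robust_range = np.percentile(x, config.range_percentile) - med
    return max(
        config.prominence_floor,
        config.noise_multiple * mad_sd,
        config.prominence_fraction * robust_range,
    )


def _find_r_peaks(x: np.ndarray, fs: float, config: DetectorConfig) -> np.ndarray:
    prominence = _prominence_threshold(x, config)
    if prominence <= 0:
        return np.empty(0, dtype=int)
    distance = max(int(round(config.refractory_s * fs)), 1)
    # pad below the global minimum so an event truncated at a segment edge
    # (R peak on the first/last sample) is still detectable
    pad = x.min() - prominence
    xp = np.concatenate([[pad], x, [pad]])
    # the height criterion keeps edge samples (whose prominence is inflated by
    # the padding) from qualifying unless they reach genuine event height
    _, props = find_peaks(
        xp, prominence=prominence, height=np.median(x) + prominence,
        distance=distance, plateau_size=(1, None)
    )
    idx = props["left_edges"].astype(int) - 1  # plateau ties -> earliest sample
    return idx[(idx >= 0) & (idx < x.size)]


def _fit_deflection(x: np.ndarray, i: int, half: int) -> float:
    """Deflection at sample ``i`` from a local parabola fit (noise-averaged)."""
    lo, hi = max(i - half, 0), min(i + half + 1, x.size)
    if hi - lo < 5:
        return float(x[i])
    u = np.arange(lo, hi, dtype=float) - i
    c = np.polyfit(u, x[lo:hi], 2)
    if c[0] == 0:
        return float(x[i])
    uv = float(np.clip(-c[1] / (2 * c[0]), -half, half))
    return float(np.polyval(c, uv))


def detect_beats(
    segment: RecordingSegment, config: DetectorConfig = MCG_DETECTOR
) -> BeatSeries:
    """Locate R and S peaks in a single-channel trace.

    A flat or all-NaN trace yields an empty :class:`BeatSeries` with a logged
    warning rather than an exception (an amotile recording is a result, not a
    failure).  Deflections are reported on the original (undetrended) signal.
    """
    seg = segment.measurement()
    x_raw = seg.signal
    if x_raw.ndim != 1:
        raise UndefinedMetricError("detect_beats expects a single channel")
    if not np.all(np.isfinite(x_raw)) or np.ptp(x_raw) == 0:
        log.warning("flat or non-finite trace %r: no beats detected", seg.label)
        return BeatSeries([], duration=seg.duration)

    x = x_raw
    if config.detrend:
        first_pass = _find_r_peaks(x_raw, seg.sampling_rate, config)
        if first_pass.size >= 2:
            period = float(np.median(np.diff(first_pass))) / seg.sampling_rate
        else:
            period = 1.0
        win = max(int(round(config.detrend_periods * period * seg.sampling_rate)), 3)
        x = x_raw - median_filter(x_raw, size=win, mode="nearest")

    r_idx = _find_r_peaks(x, seg.sampling_rate, config)
    half = int(round(config.fit_window_s * seg.sampling_rate))
    events: list[BeatEvent] = []
    bounds = np.append(r_idx[1:], x.shape[0])
    for r, nxt in zip(r_idx, bounds):
        if nxt - r < 2:
            continue
        window = x_raw[r + 1 : nxt]
        s = r + 1 + int(np.argmin(window))
        r_defl = _fit_deflection(x_raw, r, half)
        s_defl = _fit_deflection(x_raw, s, half)
        if r_defl <= s_defl:
            continue
        events.append(
            BeatEvent(
                r_time=seg.time[r],
                r_deflection=r_defl,
                s_time=seg.time[s],
                s_deflection=s_defl,
            )
        )
    return BeatSeries(events, duration=seg.duration)


def beat_rate(series: BeatSeries) -> float:
    """Beat rate in bpm, defined as 60 / mean(R-R).

    This definition is insensitive to partial beats at the segment edges; the
    event-count rate is available as ``len(series) / series.duration``.
    """
    br = series.beat_rate
    if br is None:
        raise UndefinedMetricError("beat rate requires at least 2 events")
    return br


def contraction_force(series: BeatSeries) -> float:
    """Mean R-S amplitude (contraction force, nN for MCG)."""
    if len(series) == 0:
        raise UndefinedMetricError("contraction force requires at least 1 event")
    return float(np.mean(series.rs_amplitudes))


def normalize_to_baseline(
    treatment: dict[str, float],
    baseline: dict[str, float],
    control_ratios: dict[str, float] | None = None,
) -> dict[str, RelativeResponse]:
    """Relative response per metric: treatment mean / baseline mean.

    ``control_ratios`` optionally supplies a control-group mean ratio per
    metric for the second-stage normalization used in dose-response plots
    (relative response further divided by the control mean).
    """
    out: dict[str, RelativeResponse] = {}
    for name, value in treatment.items():
        if name not in baseline:
            raise NormalizationError(f"no baseline value for metric {name!r}")
        ctrl = (control_ratios or {}).get(name, 1.0)
        out[name] = RelativeResponse(
            metric=name,
            treatment_mean=value,
            baseline_mean=baseline[name],
            control_ratio=ctrl,
        )
    return out


def series_metrics(series: BeatSeries, include_force: bool = True) -> dict[str, float]:
    """Per-segment summary metrics (beat rate, optionally contraction force)."""
    out = {"beat_rate": beat_rate(series)}
    if include_force:
        out["contraction_force"] = contraction_force(series)
    return out
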
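"""Multichannel field-potential (MEA) beat analysis with channel QC.

Extracellular field-potential amplitudes on an MEA depend on electrode
coupling, not on contraction strength, so only rate metrics (R-R intervals
and beat rate) are propagated to recording-level summaries — amplitudes never
leave the per-channel layer.

Channel quality control rejects a channel if any of:

* its spike count is implausibly low (fewer than ``min_spikes`` detections);
* its spike SNR (median detected peak amplitude over the MAD-based robust
  noise SD) falls below ``snr_floor``;
* its beat count deviates from the across-channel median count by more than
  ``count_tolerance`` (the "non-representative" channel rule).

At least 3 accepted channels are required for a valid recording-level result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beat_detection import MEA_DETECTOR, DetectorConfig, detect_beats
from .core import BeatSeries, RecordingSegment
from .errors import InputError, RecordingRejectedError

__all__ = ["MeaQcConfig", "ChannelQCReport", "MeaResult", "qc_channels", "mea_beat_series"]

MIN_ACCEPTED_CHANNELS = 3


@dataclass(frozen=True)
class MeaQcConfig:
    snr_floor: float = 5.0
    count_tolerance: float = 0.2   # fractional deviation from the median count
    min_spikes: int = 3
    detector: DetectorConfig = field(default_factory=lambda: MEA_DETECTOR)


@dataclass
class ChannelQCReport:
    channel: int
    snr: float
    n_beats: int
    count_consistent: bool
    accepted: bool


@dataclass
class MeaResult:
    """Recording-level MEA summary: rate metrics only, by design."""

    beat_rate: float                 # mean of accepted per-channel beat rates
    rr_intervals: np.ndarray         # from the highest-SNR accepted channel
    representative_channel: int
    per_channel: dict[int, BeatSeries]
    qc: list[ChannelQCReport]


def _channel_snr(segment: RecordingSegment, series: BeatSeries) -> float:
    x = segment.signal
    med = np.median(x)
    noise_sd = 1.4826 * np.median(np.abs(x - med))
    if len(series) == 0:
        return 0.0
    peak = np.median([e.r_deflection - med for e in series.events])
    if noise_sd == 0:
        return float("inf") if peak > 0 else 0.0
    return float(peak / noise_sd)


def qc_channels(
    recording: RecordingSegment, config: MeaQcConfig | None = None
) -> list[ChannelQCReport]:
    """Quality-control every channel; raises if fewer than 3 survive."""
    config = config or MeaQcConfig()
    if recording.n_channels < MIN_ACCEPTED_CHANNELS:
        raise InputError(
            f"MEA recording must have at least {MIN_ACCEPTED_CHANNELS} channels"
        )
    series: dict[int, BeatSeries] = {}
    snrs: dict[int, float] = {}
    for ch in range(recording.n_channels):
        seg = recording.channel(ch)
        s = detect_beats(seg, config.detector)
        series[ch] = s
        snrs[ch] = _channel_snr(seg.measurement(), s)

    counts = np.array([len(series[ch]) for ch in range(recording.n_channels)])
    median_count = float(np.median(counts))
    reports = []
    for ch in range(recording.n_channels):
        consistent = (
            median_count > 0
            and abs(counts[ch] - median_count) <= config.count_tolerance * median_count
        )
        accepted = (
            counts[ch] >= config.min_spikes
            and snrs[ch] >= config.snr_floor
            and consistent
        )
        reports.append(
            ChannelQCReport(
                channel=ch,
                snr=snrs[ch],
                n_beats=int(counts[ch]),
                count_consistent=bool(consistent),
                accepted=bool(accepted),
            )
        )
    if sum(r.accepted for r in reports) < MIN_ACCEPTED_CHANNELS:
        raise RecordingRejectedError(
            "fewer than 3 channels passed QC; recording rejected"
        )
    return reports


def mea_beat_series(
    recording: RecordingSegment,
    qc: list[ChannelQCReport] | None = None,
    config: MeaQcConfig | None = None,
) -> MeaResult:
    """Per-channel beat series plus the recording-level rate summary.

    Recording beat rate is the mean of accepted per-channel beat rates; the
    recording R-R sequence (used for arrhythmia scoring) is taken from the
    single accepted channel with the highest SNR, which avoids cross-channel
    interval-merging artifacts.
    """
    config = config or MeaQcConfig()
    if qc is None:
        qc = qc_channels(recording, config)
    accepted = [r for r in qc if r.accepted]
    if len(accepted) < MIN_ACCEPTED_CHANNELS:
        raise RecordingRejectedError("fewer than 3 accepted channels")

    per_channel: dict[int, BeatSeries] = {}
    rates = []
    for r in accepted:
        s = detect_beats(recording.channel(r.channel), config.detector)
        per_channel[r.channel] = s
        if s.beat_rate is None:
            raise RecordingRejectedError(
                f"accepted channel {r.channel} has < 2 beats"
            )
        rates.append(s.beat_rate)

    rep = max(accepted, key=lambda r: r.snr).channel
    return MeaResult(
        beat_rate=float(np.mean(rates)),
        rr_intervals=per_channel[rep].rr_intervals,
        representative_channel=rep,
        per_channel=per_channel,
        qc=qc,
    )
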
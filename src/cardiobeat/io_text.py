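"""Delimited-text I/O conventions.

All recordings and tables are plain comma-separated text with ``#``-prefixed
header lines carrying metadata (``key: value``).  Ground truth travels as a
JSON sidecar next to the recording it describes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BeatSeries, GroundTruth, RecordingSegment
from .errors import InputError

__all__ = [
    "write_segment",
    "read_segment",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
    "beat_series_table",
]


def write_segment(path: str | Path, segment: RecordingSegment) -> Path:
    """Write a recording as (time, signal...) CSV with a commented header."""
    path = Path(path)
    sig = segment.signal
    if sig.ndim == 1:
        cols = ["signal"]
        data = np.column_stack([segment.time, sig])
    else:
        cols = [f"ch{i}" for i in range(sig.shape[1])]
        data = np.column_stack([segment.time, sig])
    with open(path, "w") as fh:
        fh.write("# cardiobeat recording\n")
        fh.write(f"# units: {segment.units}\n")
        fh.write(f"# sampling_rate_hz: {segment.sampling_rate!r}\n")
        fh.write(f"# label: {segment.label}\n")
        fh.write(f"# stabilization_s: {segment.stabilization_s!r}\n")
        fh.write("time," + ",".join(cols) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.9g")
    return path


def _read_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_segment(path: str | Path) -> RecordingSegment:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise InputError(f"{path}: no 'time' column")
    try:
        fs = float(meta["sampling_rate_hz"])
    except KeyError as exc:
        raise InputError(f"{path}: missing sampling_rate_hz header") from exc
    sig = df.drop(columns="time").to_numpy()
    if sig.shape[1] == 1:
        sig = sig[:, 0]
    return RecordingSegment(
        time=df["time"].to_numpy(),
        signal=sig,
        sampling_rate=fs,
        units=meta.get("units", "au"),
        label=meta.get("label", ""),
        stabilization_s=float(meta.get("stabilization_s", 0.0)),
    )


def write_ground_truth(path: str | Path, gt: GroundTruth) -> Path:
    path = Path(path)
    payload = {
        "beat_times": np.asarray(gt.beat_times).tolist(),
        "amplitudes": None if gt.amplitudes is None else np.asarray(gt.amplitudes).tolist(),
        "pause_indices": np.asarray(gt.pause_indices).tolist(),
        "spark_times": np.asarray(gt.spark_times).tolist(),
        "transient_times": np.asarray(gt.transient_times).tolist(),
        "bad_channels": np.asarray(gt.bad_channels).tolist(),
        "duration": gt.duration,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        beat_times=np.asarray(d["beat_times"], dtype=float),
        amplitudes=None if d.get("amplitudes") is None
        else np.asarray(d["amplitudes"], dtype=float),
        pause_indices=np.asarray(d["pause_indices"], dtype=int),
        spark_times=np.asarray(d["spark_times"], dtype=float),
        transient_times=np.asarray(d["transient_times"], dtype=float),
        bad_channels=np.asarray(d.get("bad_channels", []), dtype=int),
        duration=float(d["duration"]),
    )


def write_table(path: str | Path, df: pd.DataFrame, comments: list[str] | None = None) -> Path:
    """Write a tidy table as CSV with optional leading '#' comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return path


def beat_series_table(series: BeatSeries) -> pd.DataFrame:
    """Per-event table: r_time, r_defl, s_time, s_defl, rr, rs."""
    rows = []
    for i, e in enumerate(series.events):
        rows.append({
            "r_time": e.r_time,
            "r_deflection": e.r_deflection,
            "s_time": e.s_time,
            "s_deflection": e.s_deflection,
            "rr": series.rr_intervals[i - 1] if i > 0 else np.nan,
            "rs": e.rs_amplitude,
        })
    return pd.DataFrame(rows)
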
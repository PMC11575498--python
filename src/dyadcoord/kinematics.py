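"""Hand-speed extraction and preprocessing.

From marker coordinates sampled at ``fps`` the scalar speed at frame
``f-1`` is the Euclidean displacement between consecutive frames divided by
the frame interval::

    speed[f-1] = sqrt((x[f] - x[f-1])**2 + (y[f] - y[f-1])**2) * fps

yielding ``n - 1`` samples for ``n`` frames. Before correlation or
information-theoretic analysis each series is preprocessed in three steps:

1. trim to the expected session length (surplus removed from the end),
2. replace local outliers (more than ``nsd`` local standard deviations from
   the local mean over a centered 1-s window) by linear interpolation,
3. smooth with a centered moving mean (0.5-s window).

Speed — not velocity — is deliberate: it captures the temporal coherence of
movement while remaining indifferent to movement form and direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, LengthError, ParameterError
from .pose_io import MarkerId, PoseTrack

__all__ = [
    "SpeedSeries",
    "compute_speed",
    "trim_series",
    "remove_outliers",
    "smooth",
    "preprocess",
    "write_speed_csv",
]


@dataclass
class SpeedSeries:
    """Scalar hand speed (px/s) at the coordinate sampling rate.

    ``values`` has length ``n - 1`` for ``n`` coordinate frames.
    ``outlier_fraction`` is the fraction of samples replaced during outlier
    removal (0 until :func:`remove_outliers` runs).
    """

    fps: float
    values: np.ndarray
    marker: MarkerId
    outlier_fraction: float = 0.0

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Session span in seconds ((len + 1) coordinate frames / fps)."""
        return (len(self) + 1) / self.fps


def compute_speed(track: PoseTrack, marker: MarkerId) -> SpeedSeries:
    """Frame-to-frame speed of one marker."""
    arr = track.data[marker]
    if arr.shape[0] < 2:
        raise InputError(f"marker {marker}: need >= 2 frames, got {arr.shape[0]}")
    d = np.diff(arr[:, :2], axis=0)
    values = np.hypot(d[:, 0], d[:, 1]) * track.fps
    return SpeedSeries(fps=track.fps, values=values, marker=marker)


def trim_series(series: SpeedSeries, expected_frames: int) -> SpeedSeries:
    """Cut the series to ``expected_frames - 1`` samples, dropping the end.

    Sessions shorter than expected are an error: only surplus is trimmed.
    """
    target = expected_frames - 1
    if len(series) < target:
        raise LengthError(
            f"series has {len(series)} samples, expected at least {target}"
        )
    if len(series) == target:
        return series
    return replace(series, values=series.values[:target].copy())


def _window_samples(window_s: float, fps: float, minimum: int) -> int:
    w = int(round(window_s * fps))
    if w < minimum:
        raise ParameterError(
            f"window of {window_s} s at {fps} fps gives {w} samples; need >= {minimum}"
        )
    return w


def remove_outliers(
    series: SpeedSeries, window: float = 1.0, nsd: float = 3.0
) -> SpeedSeries:
    """Replace local outliers by linear interpolation.

    A sample is an outlier when it lies more than ``nsd`` local standard
    deviations from the local mean, both computed over a centered window of
    ``window`` seconds (forced odd so the window is symmetric). Statistics
    are taken on the raw series in a single pass; replacements interpolate
    between the nearest retained neighbours, and leading/trailing outliers
    take the nearest retained value. Zero-variance windows flag nothing.
    """
    w = _window_samples(window, series.fps, 3)
    if w % 2 == 0:
        w += 1
    s = pd.Series(series.values)
    local_mean = s.rolling(w, center=True, min_periods=1).mean().to_numpy()
    local_sd = s.rolling(w, center=True, min_periods=2).std().to_numpy()
    with np.errstate(invalid="ignore"):
        out = np.abs(series.values - local_mean) > nsd * np.nan_to_num(local_sd)
    out &= np.nan_to_num(local_sd) > 0
    values = series.values.copy()
    if out.any():
        idx = np.arange(len(values))
        keep = idx[~out]
        if keep.size == 0:
            raise InputError("every sample flagged as outlier; series unusable")
        values[out] = np.interp(idx[out], keep, values[keep])
    return replace(
        series, values=values, outlier_fraction=float(out.mean())
    )


def smooth(series: SpeedSeries, window: float = 0.5) -> SpeedSeries:
    """Centered moving-mean smoothing (default 0.5 s); edges shrink."""
    w = _window_samples(window, series.fps, 1)
    values = (
        pd.Series(series.values)
        .rolling(w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(series, values=values)


def preprocess(
    track: PoseTrack,
    expected_frames: int,
    outlier_window: float = 1.0,
    outlier_nsd: float = 3.0,
    smooth_window: float = 0.5,
) -> dict[MarkerId, SpeedSeries]:
    """Speed + three-step preprocessing (trim, de-outlier, smooth) for all
    four hand markers."""
    out: dict[MarkerId, SpeedSeries] = {}
    for marker in track.markers:
        s = compute_speed(track, marker)
        s = trim_series(s, expected_frames)
        s = remove_outliers(s, window=outlier_window, nsd=outlier_nsd)
        s = smooth(s, window=smooth_window)
        out[marker] = s
    return out


def write_speed_csv(
    speeds: dict[MarkerId, SpeedSeries], path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Long-format speed CSV (frame_index, marker, speed) plus an optional
    JSON sidecar with per-marker outlier fractions."""
    frames = np.arange(len(next(iter(speeds.values()))))
    df = pd.concat(
        [
            pd.DataFrame(
                {"frame_index": frames, "marker": str(m), "speed": s.values}
            )
            for m, s in sorted(speeds.items())
        ],
        ignore_index=True,
    )
    df.to_csv(path, index=False)
    if sidecar is not None:
        Path(sidecar).write_text(
            json.dumps(
                {str(m): s.outlier_fraction for m, s in sorted(speeds.items())},
                indent=2,
            )
        )
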
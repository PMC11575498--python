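"""Reading, writing and conditioning of hand-marker coordinate tracks.

Two on-disk dialects are supported:

* the DeepLabCut output CSV (three header rows ``scorer`` / ``bodyparts`` /
  ``coords`` with an ``x, y, likelihood`` triplet per body part), and
* a plain long-format CSV with columns
  ``frame,participant,hand,x,y,likelihood``.

Both load into a :class:`PoseTrack`, which holds per-frame ``(x, y,
likelihood)`` for the four hand markers of a dyad (participants A and B,
left and right hand). Conditioning follows the usual pose-estimation
practice: samples whose tracker likelihood falls below a cutoff are treated
as missing and bridged by linear interpolation, and coordinates are
median-filtered to suppress single-frame tracker glitches.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    FormatError,
    InputError,
    ParameterError,
    ParseError,
    UnusableMarkerError,
)

__all__ = [
    "MarkerId",
    "PoseTrack",
    "CANONICAL_MARKERS",
    "DEFAULT_MARKER_MAP",
    "read_dlc_csv",
    "write_dlc_csv",
    "read_plain_csv",
    "write_plain_csv",
    "apply_pcutoff",
    "median_filter_track",
]


@dataclass(frozen=True, order=True)
class MarkerId:
    """One tracked hand: which participant (``A``/``B``) and which hand."""

    participant: str
    hand: str

    def __post_init__(self) -> None:
        if self.participant not in ("A", "B"):
            raise ConfigError(f"participant must be 'A' or 'B', got {self.participant!r}")
        if self.hand not in ("left", "right"):
            raise ConfigError(f"hand must be 'left' or 'right', got {self.hand!r}")

    def __str__(self) -> str:  # e.g. "A_left"
        return f"{self.participant}_{self.hand}"


#: The four markers every session must provide.
CANONICAL_MARKERS: tuple[MarkerId, ...] = (
    MarkerId("A", "left"),
    MarkerId("A", "right"),
    MarkerId("B", "left"),
    MarkerId("B", "right"),
)

#: Default body-part-name -> marker mapping used when a project names its
#: parts "A_left", "A_right", ... Projects with other naming conventions pass
#: their own mapping.
DEFAULT_MARKER_MAP: dict[str, MarkerId] = {str(m): m for m in CANONICAL_MARKERS}


@dataclass
class PoseTrack:
    """Per-frame marker coordinates for one session.

    ``data`` maps each :class:`MarkerId` to an ``(n, 3)`` float array of
    ``x, y, likelihood``; ``missing`` maps it to a boolean mask of samples
    that were below the likelihood cutoff (filled by interpolation).
    """

    fps: float
    data: dict[MarkerId, np.ndarray]
    missing: dict[MarkerId, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {arr.shape[0] for arr in self.data.values()}
        if len(lengths) > 1:
            raise InputError(f"marker sequences have unequal lengths: {sorted(lengths)}")
        for m, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InputError(f"marker {m} array must have shape (n, 3)")
            lik = arr[:, 2]
            if np.any((lik < 0) | (lik > 1) | ~np.isfinite(lik)):
                raise InputError(f"marker {m} likelihoods outside [0, 1]")
        if not self.missing:
            self.missing = {
                m: np.zeros(arr.shape[0], dtype=bool) for m, arr in self.data.items()
            }

    @property
    def frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def markers(self) -> tuple[MarkerId, ...]:
        return tuple(sorted(self.data))

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            fps=self.fps,
            data={m: arr.copy() for m, arr in self.data.items()},
            missing={m: msk.copy() for m, msk in self.missing.items()},
        )


def _require_hand_markers(found: Mapping[str, MarkerId], available: set[str]) -> None:
    missing = [name for name in found if name not in available]
    if missing:
        raise ConfigError(
            f"marker mapping names body parts absent from the file: {missing}; "
            f"available: {sorted(available)}"
        )
    mapped = set(found.values())
    if mapped != set(CANONICAL_MARKERS):
        raise ConfigError(
            f"marker mapping must cover exactly the four hand markers "
            f"{[str(m) for m in CANONICAL_MARKERS]}, got {[str(m) for m in sorted(mapped)]}"
        )


def read_dlc_csv(
    path: str | Path,
    marker_map: Mapping[str, MarkerId] | None = None,
    fps: float = 60.0,
) -> PoseTrack:
    """Read a DeepLabCut-dialect CSV into a :class:`PoseTrack`.

    ``marker_map`` maps body-part names (as they appear in the ``bodyparts``
    header row) to the four hand markers; body parts not named in the mapping
    are ignored (pose projects typically over-label).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise FormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    labels = [rows[i][0].strip().lower() for i in range(3)]
    if labels != ["scorer", "bodyparts", "coords"]:
        raise FormatError(
            f"{path}: header rows must start with scorer/bodyparts/coords, got {labels}"
        )
    bodyparts = rows[1][1:]
    coords = rows[2][1:]
    ncols = len(bodyparts)
    if len(coords) != ncols:
        raise FormatError(f"{path}: bodyparts/coords header rows have unequal width")
    # group columns into (bodypart -> {coord: column index})
    columns: dict[str, dict[str, int]] = {}
    for j, (bp, co) in enumerate(zip(bodyparts, coords)):
        columns.setdefault(bp, {})[co.strip().lower()] = j + 1
    for bp, cols in columns.items():
        if set(cols) != {"x", "y", "likelihood"}:
            raise FormatError(
                f"{path}: body part {bp!r} lacks an x,y,likelihood triplet"
            )

    mapping = dict(marker_map) if marker_map is not None else dict(DEFAULT_MARKER_MAP)
    _require_hand_markers(mapping, set(columns))

    body = rows[3:]
    width = len(rows[1])
    data: dict[MarkerId, np.ndarray] = {}
    try:
        values = np.empty((len(body), width - 1), dtype=float)
        for i, row in enumerate(body):
            if len(row) != width:
                raise ParseError(
                    f"{path}: row {i + 4} has {len(row)} fields, expected {width}"
                )
            values[i] = [float(v) for v in row[1:]]
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value in data rows: {exc}") from exc

    for name, marker in mapping.items():
        cols = columns[name]
        arr = np.column_stack(
            [values[:, cols["x"] - 1], values[:, cols["y"] - 1], values[:, cols["likelihood"] - 1]]
        )
        data[marker] = arr
    return PoseTrack(fps=fps, data=data)


def write_dlc_csv(
    track: PoseTrack,
    path: str | Path,
    marker_names: Mapping[MarkerId, str] | None = None,
    scorer: str = "dyadcoord",
) -> None:
    """Write a :class:`PoseTrack` in the DeepLabCut CSV dialect.

    Coordinates are written with :func:`repr` so a read/write cycle is
    bit-exact.
    """
    names = (
        dict(marker_names)
        if marker_names is not None
        else {m: str(m) for m in track.markers}
    )
    markers = list(track.markers)
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * len(markers)))
        w.writerow(["bodyparts"] + [names[m] for m in markers for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(markers))
        for f in range(track.frames):
            row: list[object] = [f]
            for m in markers:
                x, y, lik = track.data[m][f]
                row.extend([repr(float(x)), repr(float(y)), repr(float(lik))])
            w.writerow(row)


def read_plain_csv(path: str | Path, fps: float = 60.0) -> PoseTrack:
    """Read the plain long-format dialect: frame,participant,hand,x,y,likelihood."""
    df = pd.read_csv(path)
    required = {"frame", "participant", "hand", "x", "y", "likelihood"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: plain CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    data: dict[MarkerId, np.ndarray] = {}
    for (participant, hand), grp in df.groupby(["participant", "hand"]):
        marker = MarkerId(str(participant), str(hand))
        grp = grp.sort_values("frame")
        data[marker] = grp[["x", "y", "likelihood"]].to_numpy(dtype=float)
    if set(data) != set(CANONICAL_MARKERS):
        raise ConfigError(
            f"{path}: expected the four hand markers, got {[str(m) for m in sorted(data)]}"
        )
    return PoseTrack(fps=fps, data=data)


def write_plain_csv(track: PoseTrack, path: str | Path) -> None:
    rows = []
    for m in track.markers:
        arr = track.data[m]
        for f in range(arr.shape[0]):
            rows.append(
                {
                    "frame": f,
                    "participant": m.participant,
                    "hand": m.hand,
                    "x": arr[f, 0],
                    "y": arr[f, 1],
                    "likelihood": arr[f, 2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def apply_pcutoff(track: PoseTrack, cutoff: float) -> PoseTrack:
    """Mask samples with tracker likelihood below ``cutoff`` and bridge them.

    Masked coordinates are filled by 1-D linear interpolation between the
    nearest retained samples (leading/trailing gaps take the nearest retained
    value), preserving the fixed sampling grid. The mask is recorded in
    ``missing``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError(f"cutoff must be in [0, 1], got {cutoff}")
    out = track.copy()
    for m, arr in out.data.items():
        below = arr[:, 2] < cutoff
        if below.all():
            raise UnusableMarkerError(
                f"marker {m}: all {arr.shape[0]} samples below likelihood cutoff {cutoff}"
            )
        if below.any():
            idx = np.arange(arr.shape[0])
            keep = idx[~below]
            for c in (0, 1):
                arr[below, c] = np.interp(idx[below], keep, arr[keep, c])
        out.missing[m] = out.missing[m] | below
    return out


def median_filter_track(track: PoseTrack, window: int = 5) -> PoseTrack:
    """Centered rolling-median filter on each coordinate sequence.

    ``window`` must be odd; at the edges the window shrinks to the available
    samples. Likelihoods are left untouched.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"median filter window must be odd and >= 1, got {window}")
    out = track.copy()
    for m, arr in out.data.items():
        for c in (0, 1):
            arr[:, c] = (
                pd.Series(arr[:, c])
                .rolling(window, center=True, min_periods=1)
                .median()
                .to_numpy()
            )
    return out
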
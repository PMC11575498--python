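"""Maximum correlation vector (MCV) and data-sliding significance test.

Temporal alignment of the dancers' movement is measured with rolling-window
Spearman correlations (default window 5 s, step 1 sample) between the speed
series of every between-participant hand pairing (A-left→B-left,
A-left→B-right, A-right→B-left, A-right→B-right). The MCV is the pointwise
maximum over those four correlation vectors, assigning equal importance to
all forms of hand coordination regardless of how many hands take part.

Significance is assessed with a surrogate ("data sliding") test: one
participant's series is cut at a uniformly random point and the two pieces
swapped, destroying cross-alignment while preserving autocorrelation; the
MCV is recomputed against the partner's intact series. Repeating this
(default 1,000 slides) within a moment and pooling the shuffled MCV values
gives a null distribution whose 95th percentile serves as the moment's
significance threshold.

Windows are centered; positions whose window would overrun an edge, or in
which either series has zero variance, are undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError, ParameterError, UndefinedThresholdError
from .kinematics import SpeedSeries
from .pose_io import CANONICAL_MARKERS, MarkerId

__all__ = [
    "PAIRINGS",
    "CorrelationVector",
    "MCVSeries",
    "SignificanceThreshold",
    "rolling_spearman",
    "max_correlation_vector",
    "mcv_from_speeds",
    "slide_series",
    "significance_threshold",
    "write_mcv_csv",
]

#: The four between-participant hand pairings, in canonical order.
PAIRINGS: tuple[tuple[MarkerId, MarkerId], ...] = (
    (MarkerId("A", "left"), MarkerId("B", "left")),
    (MarkerId("A", "left"), MarkerId("B", "right")),
    (MarkerId("A", "right"), MarkerId("B", "left")),
    (MarkerId("A", "right"), MarkerId("B", "right")),
)


@dataclass
class CorrelationVector:
    """Rolling Spearman correlation for one hand pairing.

    ``values`` is aligned with the input speed samples; undefined positions
    (edges, zero-variance windows) are NaN.
    """

    pairing: tuple[MarkerId, MarkerId]
    values: np.ndarray
    window: float

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MCVSeries:
    """Pointwise maximum over the four pairing correlation vectors."""

    values: np.ndarray
    source_pairing: np.ndarray  # index into PAIRINGS, -1 where undefined
    window: float
    fps: float

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SignificanceThreshold:
    """Result of the data-sliding test for one moment."""

    threshold: float
    n_slides: int
    percentile: float
    seed: int
    slid_participant: str
    pool: np.ndarray = field(repr=False)  # all defined shuffled MCV values


def _rank_windows(values: np.ndarray, w: int, circular: bool = False):
    """Within-window average ranks plus per-window mean/SD.

    Returns ``(ranks, mean, sd)`` where ``ranks`` has one row per window
    start; with ``circular=True`` there are ``n`` rows (windows wrap around),
    otherwise ``n - w + 1``.
    """
    v = np.concatenate([values, values[: w - 1]]) if circular else values
    win = np.lib.stride_tricks.sliding_window_view(v, w)
    ranks = rankdata(win, axis=1, method="average").astype(np.float64)
    mean = ranks.mean(axis=1)
    sd = ranks.std(axis=1)
    # zero within-window variance of the *data* => all ranks tied => sd 0
    return ranks, mean, sd


def _corr_rows(rx, mx, sx, ry, my, sy) -> np.ndarray:
    """Pearson correlation of pre-ranked windows, row by row (NaN when a
    window is degenerate)."""
    w = rx.shape[1]
    dot = np.einsum("ij,ij->i", rx, ry) / w
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (dot - mx * my) / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, SpeedSeries) else np.asarray(x, dtype=float)


def _center_pad(rho_win: np.ndarray, n: int, w: int) -> np.ndarray:
    """Place per-window correlations at window centers in a length-n array."""
    out = np.full(n, np.nan)
    out[(w - 1) // 2 : (w - 1) // 2 + rho_win.shape[0]] = rho_win
    return out


def rolling_spearman(
    x: SpeedSeries | np.ndarray,
    y: SpeedSeries | np.ndarray,
    window: float = 5.0,
    fps: float | None = None,
    pairing: tuple[MarkerId, MarkerId] | None = None,
) -> CorrelationVector:
    """Centered rolling-window Spearman correlation (step = 1 sample).

    Ranks use the average-rank convention for ties, so each window's value
    equals SciPy's ``spearmanr`` on that window.
    """
    if fps is None:
        fps = x.fps if isinstance(x, SpeedSeries) else 60.0
    xv, yv = _as_values(x), _as_values(y)
    if xv.shape != yv.shape:
        raise InputError(f"series lengths differ: {xv.shape} vs {yv.shape}")
    w = int(round(window * fps))
    if w < 3:
        raise ParameterError(f"window of {window} s at {fps} fps is {w} samples; need >= 3")
    if xv.shape[0] < w:
        raise InputError(f"series shorter ({xv.shape[0]}) than one window ({w})")
    rx, mx, sx = _rank_windows(xv, w)
    ry, my, sy = _rank_windows(yv, w)
    rho = _corr_rows(rx, mx, sx, ry, my, sy)
    if pairing is None:
        pairing = PAIRINGS[0]
    return CorrelationVector(
        pairing=pairing, values=_center_pad(rho, xv.shape[0], w), window=window
    )


def max_correlation_vector(cvs: Sequence[CorrelationVector]) -> MCVSeries:
    """Pointwise maximum over the four pairing correlation vectors.

    Positions where every vector is undefined stay undefined; elsewhere the
    maximum is over the defined values and the winning pairing is recorded.
    """
    if {cv.pairing for cv in cvs} != set(PAIRINGS):
        raise InputError(
            "expected exactly the four between-participant hand pairings"
        )
    ordered = sorted(cvs, key=lambda cv: PAIRINGS.index(cv.pairing))
    lengths = {len(cv) for cv in ordered}
    if len(lengths) != 1:
        raise InputError(f"correlation vectors have unequal lengths: {sorted(lengths)}")
    stack = np.vstack([cv.values for cv in ordered])
    all_nan = np.isnan(stack).all(axis=0)
    filled = np.where(np.isnan(stack), -np.inf, stack)
    values = filled.max(axis=0)
    source = filled.argmax(axis=0).astype(np.int64)
    values[all_nan] = np.nan
    source[all_nan] = -1
    cv0 = ordered[0]
    fps = 60.0
    return MCVSeries(values=values, source_pairing=source, window=cv0.window, fps=fps)


def mcv_from_speeds(
    speeds: Mapping[MarkerId, SpeedSeries], window: float = 5.0
) -> tuple[list[CorrelationVector], MCVSeries]:
    """Convenience: the four pairing correlation vectors and their maximum."""
    missing = [m for m in CANONICAL_MARKERS if m not in speeds]
    if missing:
        raise InputError(f"missing speed series for markers: {missing}")
    fps = speeds[CANONICAL_MARKERS[0]].fps
    cvs = [
        rolling_spearman(speeds[a], speeds[b], window=window, fps=fps, pairing=(a, b))
        for a, b in PAIRINGS
    ]
    mcv = max_correlation_vector(cvs)
    mcv.fps = fps
    return cvs, mcv


def slide_series(x: SpeedSeries | np.ndarray, cut: int) -> np.ndarray:
    """Swap the two pieces of ``x`` about ``cut``: concat(x[cut:], x[:cut])."""
    xv = _as_values(x)
    if not 0 <= cut <= xv.shape[0]:
        raise ParameterError(f"cut {cut} outside [0, {xv.shape[0]}]")
    return np.concatenate([xv[cut:], xv[:cut]])


def significance_threshold(
    speeds: Mapping[MarkerId, SpeedSeries],
    start: float,
    end: float,
    n_slides: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    window: float = 5.0,
    slide_participant: str = "A",
) -> SignificanceThreshold:
    """Data-sliding significance threshold for the moment ``[start, end)`` s.

    Both hand series of ``slide_participant`` are slid jointly at one
    uniformly random cut per slide (preserving that participant's intra-body
    coupling), the MCV is recomputed against the partner's intact series,
    and all defined shuffled MCV values are pooled across slides; the
    threshold is the requested percentile of the pool (linear interpolation
    between order statistics).
    """
    if slide_participant not in ("A", "B"):
        raise ParameterError("slide_participant must be 'A' or 'B'")
    fps = speeds[CANONICAL_MARKERS[0]].fps
    n_total = len(speeds[CANONICAL_MARKERS[0]])
    # the speed grid has one sample fewer than the coordinate frames, so a
    # moment ending at the session end may overrun by one sample
    i0, i1 = int(round(start * fps)), min(int(round(end * fps)), n_total)
    w = int(round(window * fps))
    seg = {m: s.values[i0:i1] for m, s in speeds.items()}
    n = i1 - i0
    if n < w:
        raise InputError(f"moment of {n} samples shorter than one {w}-sample window")

    other = "B" if slide_participant == "A" else "A"
    slid_markers = [m for m in CANONICAL_MARKERS if m.participant == slide_participant]
    fixed_markers = [m for m in CANONICAL_MARKERS if m.participant == other]
    # ranks of the intact partner's windows are reused across all slides;
    # the slid participant's windows are circular windows of the original,
    # so a single circular precomputation covers every cut point.
    fixed = {m: _rank_windows(seg[m], w) for m in fixed_markers}
    slidr = {m: _rank_windows(seg[m], w, circular=True) for m in slid_markers}

    rng = np.random.default_rng(seed)
    cuts = rng.integers(0, n + 1, size=n_slides)
    n_win = n - w + 1
    base = np.arange(n_win)
    pools: list[np.ndarray] = []
    for cut in cuts:
        idx = (base + cut) % n
        per_pairing = []
        for ms in slid_markers:
            rx, mx, sx = (slidr[ms][0][idx], slidr[ms][1][idx], slidr[ms][2][idx])
            for mf in fixed_markers:
                ry, my, sy = fixed[mf]
                per_pairing.append(_corr_rows(rx, mx, sx, ry, my, sy))
        stack = np.vstack(per_pairing)
        all_nan = np.isnan(stack).all(axis=0)
        shuffled_mcv = np.where(np.isnan(stack), -np.inf, stack).max(axis=0)
        pools.append(shuffled_mcv[~all_nan])
    pool = np.concatenate(pools) if pools else np.empty(0)
    if pool.size == 0:
        raise UndefinedThresholdError(
            "all shuffled windows degenerate; no significance threshold"
        )
    return SignificanceThreshold(
        threshold=float(np.percentile(pool, percentile)),
        n_slides=n_slides,
        percentile=percentile,
        seed=seed,
        slid_participant=slide_participant,
        pool=pool,
    )


def write_mcv_csv(
    cvs: Sequence[CorrelationVector], mcv: MCVSeries, path: str | Path
) -> None:
    """Per-sample CSV: t, the four correlation vectors, MCV and its source."""
    ordered = sorted(cvs, key=lambda cv: PAIRINGS.index(cv.pairing))
    n = len(mcv)
    cols: dict[str, np.ndarray] = {"t": np.arange(n) / mcv.fps}
    for cv in ordered:
        cols[f"cv_{cv.pairing[0]}_{cv.pairing[1]}"] = cv.values
    cols["mcv"] = mcv.values
    cols["source_pairing"] = mcv.source_pairing
    pd.DataFrame(cols).to_csv(path, index=False)
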
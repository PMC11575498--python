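"""Windowed normalized symbolic transfer entropy (NSTE) between dancers.

Transfer entropy quantifies the predictive power of a source signal's past
for a target signal's future beyond the target's own past. The symbolic
variant works on ordinal patterns: each delay-embedded vector
``(x[t], x[t+tau], ..., x[t+(m-1)tau])`` is replaced by the lexicographic
index of its rank permutation (ties broken by earlier position), giving a
sequence over ``m!`` discrete symbols. With symbol series ``X`` (source) and
``Y`` (target) and prediction step ``delta``::

    STE(X -> Y) = sum p(y[t+d], y[t], x[t])
                  * log2( p(y[t+d] | y[t], x[t]) / p(y[t+d] | y[t]) )

estimated by plug-in counts. The normalized form subtracts a source-shuffle
bias estimate and divides by the target's conditional entropy
``H(y[t+d] | y[t])``::

    NSTE = (STE - mean_shuffles STE_shuffled) / H(y[t+d] | y[t])

which removes bias from source signal characteristics and target
autocorrelation and maps the value into [-1, 1]. The directional asymmetry
index ``(a - b)/(a + b)`` (with both values floored at 0) is positive when
information flow from A to B dominates.

Windowed analysis (default 2-s windows stepped by 0.5 s) mirrors the MCV's
pairing logic: for each window the directed NSTE is the maximum over the
four between-participant hand pairings and over the embedding delay range
``tau`` (default 6..15 samples, i.e. a 100–250 ms prediction range at
60 Hz, with ``delta = tau``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .kinematics import SpeedSeries
from .mcv import PAIRINGS
from .pose_io import CANONICAL_MARKERS, MarkerId

__all__ = [
    "NSTEParams",
    "SymbolSeries",
    "NSTEResult",
    "ordinal_symbolize",
    "ste",
    "nste",
    "nste_windowed",
    "asymmetry",
    "smooth_nonoverlapping",
]


@dataclass(frozen=True)
class NSTEParams:
    """Parameters of the windowed NSTE analysis.

    ``tau_range`` are embedding delays in samples; the prediction step
    ``delta`` equals ``tau`` unless overridden. ``tau_agg`` selects how the
    per-window value aggregates over the delay range ("max" or "mean").
    """

    m: int = 3
    tau_range: tuple[int, ...] = tuple(range(6, 16))
    delta: int | None = None
    window: float = 2.0
    step: float = 0.5
    n_shuffles: int = 10
    seed: int = 0
    tau_agg: str = "max"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ParameterError(f"embedding dimension m must be >= 2, got {self.m}")
        if not self.tau_range or min(self.tau_range) < 1:
            raise ParameterError("tau_range must be non-empty with tau >= 1")
        if self.tau_agg not in ("max", "mean"):
            raise ParameterError("tau_agg must be 'max' or 'mean'")

    def delta_for(self, tau: int) -> int:
        return self.delta if self.delta is not None else tau

    def validate_window(self, fps: float) -> None:
        w = int(round(self.window * fps))
        need = (self.m - 1) * max(self.tau_range) + max(
            self.delta_for(t) for t in self.tau_range
        )
        if w <= need:
            raise ParameterError(
                f"window of {w} samples too short for m={self.m}, "
                f"max tau={max(self.tau_range)} (needs > {need})"
            )


@dataclass
class SymbolSeries:
    """Ordinal-pattern symbols of a delay-embedded signal segment."""

    symbols: np.ndarray  # ints in [0, m!-1]
    m: int
    tau: int

    def __len__(self) -> int:
        return self.symbols.shape[0]


def ordinal_symbolize(x: SpeedSeries | np.ndarray, m: int, tau: int) -> SymbolSeries:
    """Map each embedding vector to the lexicographic index of its rank
    permutation.

    The vector at ``t`` is ``(x[t], x[t+tau], ..., x[t+(m-1)tau])``; its
    ranks are assigned with ties going to the earlier position, and the
    symbol is the index of the rank sequence among the ``m!`` permutations
    in lexicographic order. A strictly increasing segment therefore maps to
    symbol 0 everywhere.
    """
    xv = x.values if isinstance(x, SpeedSeries) else np.asarray(x, dtype=float)
    n = xv.shape[0]
    n_sym = n - (m - 1) * tau
    if n_sym <= 0:
        raise InputError(
            f"segment of {n} samples too short for m={m}, tau={tau}"
        )
    emb = np.column_stack([xv[i * tau : i * tau + n_sym] for i in range(m)])
    order = np.argsort(emb, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(m)[None, :].repeat(n_sym, 0), axis=1)
    # Lehmer code of the rank sequence -> lexicographic permutation index
    symbols = np.zeros(n_sym, dtype=np.int64)
    for i in range(m - 1):
        smaller_after = np.zeros(n_sym, dtype=np.int64)
        for j in range(i + 1, m):
            smaller_after += ranks[:, j] < ranks[:, i]
        symbols += smaller_after * factorial(m - 1 - i)
    return SymbolSeries(symbols=symbols, m=m, tau=tau)


def _triplet_counts(src: np.ndarray, tgt: np.ndarray, delta: int, k: int) -> np.ndarray:
    """Joint counts over (tgt future, tgt present, src present) as a k^3 table."""
    yf = tgt[delta:]
    yp = tgt[:-delta]
    xp = src[:-delta]
    code = (yf * k + yp) * k + xp
    return np.bincount(code, minlength=k**3).reshape(k, k, k)


def ste(src: SymbolSeries, tgt: SymbolSeries, delta: int) -> float:
    """Plug-in symbolic transfer entropy, in bits (always >= 0).

    Estimated from the empirical counts of ``(y[t+delta], y[t], x[t])``
    triplets. With fewer than two distinct target symbols the value is 0.
    """
    if len(src) != len(tgt):
        raise InputError("source and target symbol series must align")
    if src.m != tgt.m:
        raise InputError("source and target must share the embedding dimension")
    if delta < 1 or delta >= len(tgt):
        raise InputError(f"delta {delta} leaves no (future, present) pairs")
    k = factorial(tgt.m)
    c3 = _triplet_counts(src.symbols, tgt.symbols, delta, k)
    return _ste_from_counts(c3)


def _ste_from_counts(c3: np.ndarray) -> float:
    n = c3.sum()
    c_yx = c3.sum(axis=0)        # (y present, x present)
    c_yy = c3.sum(axis=2)        # (y future, y present)
    c_y = c3.sum(axis=(0, 2))    # (y present,)
    yf, yp, xp = np.nonzero(c3)
    c = c3[yf, yp, xp].astype(float)
    ratio = c * c_y[yp] / (c_yx[yp, xp] * c_yy[yf, yp])
    val = float(np.sum(c / n * np.log2(ratio)))
    return max(val, 0.0)


def _cond_entropy(tgt: np.ndarray, delta: int, k: int) -> float:
    """Empirical H(y[t+delta] | y[t]) in bits."""
    yf = tgt[delta:]
    yp = tgt[:-delta]
    c2 = np.bincount(yf * k + yp, minlength=k * k).reshape(k, k).astype(float)
    n = c2.sum()
    c1 = c2.sum(axis=0)
    f, p = np.nonzero(c2)
    c = c2[f, p]
    return float(-np.sum(c / n * np.log2(c / c1[p])))


def nste(
    src: SpeedSeries | np.ndarray,
    tgt: SpeedSeries | np.ndarray,
    m: int,
    tau: int,
    delta: int | None = None,
    n_shuffles: int = 10,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Normalized symbolic transfer entropy of one window segment.

    The shuffle bias term permutes the *source symbol sequence* uniformly
    (``n_shuffles`` draws) and averages the resulting STE; the denominator
    is the target's conditional entropy ``H(y[t+delta] | y[t])``. A constant
    target (zero conditional entropy) yields 0 by convention.
    """
    if delta is None:
        delta = tau
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = ordinal_symbolize(src, m, tau)
    t = ordinal_symbolize(tgt, m, tau)
    k = factorial(m)
    if delta >= len(t):
        raise InputError("segment too short for the prediction step")
    h = _cond_entropy(t.symbols, delta, k)
    if h == 0.0:
        return 0.0
    raw = ste(s, t, delta)
    bias = 0.0
    if n_shuffles > 0:
        for _ in range(n_shuffles):
            perm = rng.permutation(s.symbols)
            bias += _ste_from_counts(_triplet_counts(perm, t.symbols, delta, k))
        bias /= n_shuffles
    return (raw - bias) / h


@dataclass
class NSTEResult:
    """Windowed directed NSTE in both directions with asymmetry per window."""

    centers: np.ndarray          # window centers, s
    nste_ab: np.ndarray
    nste_ba: np.ndarray
    asymmetry: np.ndarray
    source_pairing_ab: np.ndarray  # index into PAIRINGS
    source_pairing_ba: np.ndarray
    tau_ab: np.ndarray
    tau_ba: np.ndarray
    params: NSTEParams = field(default_factory=NSTEParams)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_center_s": self.centers,
                "nste_ab": self.nste_ab,
                "nste_ba": self.nste_ba,
                "asymmetry": self.asymmetry,
                "source_pairing_ab": self.source_pairing_ab,
                "source_pairing_ba": self.source_pairing_ba,
                "tau_ab": self.tau_ab,
                "tau_ba": self.tau_ba,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def asymmetry(nste_ab: float, nste_ba: float) -> float:
    """Directional dominance index ``(a - b) / (a + b)`` with both values
    floored at 0; 0/0 maps to 0. Antisymmetric under argument swap."""
    a = max(float(nste_ab), 0.0)
    b = max(float(nste_ba), 0.0)
    if a + b == 0.0:
        return 0.0
    return (a - b) / (a + b)


def nste_windowed(
    speeds: Mapping[MarkerId, SpeedSeries],
    params: NSTEParams = NSTEParams(),
) -> NSTEResult:
    """Windowed directed NSTE over a session.

    For every window (default 2 s stepped by 0.5 s over the session span),
    every between-participant hand pairing and every ``tau``, NSTE is
    computed in both directions; the A→B value for the window aggregates
    (default max) over pairings and delays, and likewise B→A. Symbol
    sequences are precomputed once per hand and delay, so windows only
    slice them.
    """
    missing = [m for m in CANONICAL_MARKERS if m not in speeds]
    if missing:
        raise InputError(f"missing speed series for markers: {missing}")
    fps = speeds[CANONICAL_MARKERS[0]].fps
    params.validate_window(fps)
    n = len(speeds[CANONICAL_MARKERS[0]])
    duration = (n + 1) / fps
    w = int(round(params.window * fps))
    step = int(round(params.step * fps))
    if n < w - 1:
        raise InputError(f"series of {n} samples shorter than one {w}-sample window")
    n_win = int(np.floor((duration - params.window) / params.step)) + 1
    k = factorial(params.m)

    # symbols depend only on (hand, tau) — precompute over the full series
    sym: dict[tuple[MarkerId, int], np.ndarray] = {}
    for marker in CANONICAL_MARKERS:
        for tau in params.tau_range:
            sym[(marker, tau)] = ordinal_symbolize(
                speeds[marker], params.m, tau
            ).symbols

    rng = np.random.default_rng(params.seed)
    centers = np.empty(n_win)
    out_ab = np.empty(n_win)
    out_ba = np.empty(n_win)
    src_ab = np.empty(n_win, dtype=np.int64)
    src_ba = np.empty(n_win, dtype=np.int64)
    tau_ab = np.empty(n_win, dtype=np.int64)
    tau_ba = np.empty(n_win, dtype=np.int64)

    for iw in range(n_win):
        i0 = iw * step
        i1 = min(i0 + w, n)
        centers[iw] = (i0 / fps) + params.window / 2.0
        best_ab = best_ba = -np.inf
        acc_ab: list[float] = []
        acc_ba: list[float] = []
        b_src_ab = b_src_ba = -1
        b_tau_ab = b_tau_ba = -1
        for ip, (ma, mb) in enumerate(PAIRINGS):
            for tau in params.tau_range:
                delta = params.delta_for(tau)
                n_sym = (i1 - i0) - (params.m - 1) * tau
                if n_sym - delta < 2:
                    continue
                sa = sym[(ma, tau)][i0 : i0 + n_sym]
                sb = sym[(mb, tau)][i0 : i0 + n_sym]
                v_ab = _nste_symbols(sa, sb, delta, k, params.n_shuffles, rng)
                v_ba = _nste_symbols(sb, sa, delta, k, params.n_shuffles, rng)
                acc_ab.append(v_ab)
                acc_ba.append(v_ba)
                if v_ab > best_ab:
                    best_ab, b_src_ab, b_tau_ab = v_ab, ip, tau
                if v_ba > best_ba:
                    best_ba, b_src_ba, b_tau_ba = v_ba, ip, tau
        if params.tau_agg == "mean":
            out_ab[iw] = float(np.mean(acc_ab)) if acc_ab else np.nan
            out_ba[iw] = float(np.mean(acc_ba)) if acc_ba else np.nan
        else:
            out_ab[iw] = best_ab if np.isfinite(best_ab) else np.nan
            out_ba[iw] = best_ba if np.isfinite(best_ba) else np.nan
        src_ab[iw], src_ba[iw] = b_src_ab, b_src_ba
        tau_ab[iw], tau_ba[iw] = b_tau_ab, b_tau_ba

    asym = np.array([asymmetry(a, b) for a, b in zip(out_ab, out_ba)])
    return NSTEResult(
        centers=centers,
        nste_ab=out_ab,
        nste_ba=out_ba,
        asymmetry=asym,
        source_pairing_ab=src_ab,
        source_pairing_ba=src_ba,
        tau_ab=tau_ab,
        tau_ba=tau_ba,
        params=params,
    )


def _nste_symbols(
    src: np.ndarray,
    tgt: np.ndarray,
    delta: int,
    k: int,
    n_shuffles: int,
    rng: np.random.Generator,
) -> float:
    """NSTE from precomputed symbol slices (fast path for windowing)."""
    h = _cond_entropy(tgt, delta, k)
    if h == 0.0:
        return 0.0
    raw = _ste_from_counts(_triplet_counts(src, tgt, delta, k))
    bias = 0.0
    if n_shuffles > 0:
        for _ in range(n_shuffles):
            perm = rng.permutation(src)
            bias += _ste_from_counts(_triplet_counts(perm, tgt, delta, k))
        bias /= n_shuffles
    return (raw - bias) / h


def smooth_nonoverlapping(
    t: np.ndarray, values: np.ndarray, window: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Display smoothing: mean per consecutive non-overlapping ``window``-s
    bin, timestamped at the bin center. Bins are anchored at the first
    timestamp; the covered span counts one sample interval per point, and a
    trailing partial bin is dropped."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.shape != values.shape:
        raise InputError("timestamps and values must align")
    if t.size == 0:
        return t, values
    dt = t[1] - t[0] if t.size > 1 else window
    span = t[-1] - t[0] + dt
    n_bins = int(np.floor(span / window))
    if n_bins < 1:
        raise InputError(f"series spans {span} s, shorter than one {window}-s bin")
    centers = np.empty(n_bins)
    means = np.empty(n_bins)
    for b in range(n_bins):
        lo = t[0] + b * window
        hi = lo + window
        sel = (t >= lo) & (t < hi)
        centers[b] = lo + window / 2.0
        means[b] = float(np.nanmean(values[sel])) if sel.any() else np.nan
    return centers, means
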
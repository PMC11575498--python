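"""Synthetic dyad sessions with scripted ground-truth coordination episodes.

The simulator emulates two participants x two hands of ``(x, y,
likelihood)`` at 60 Hz on a bounded table surface, with a script of
non-overlapping episodes:

* ``coupled`` — one participant leads; each follower hand's speed is a
  convex mixture ``alpha * leader speed delayed by lag + (1 - alpha) * own
  noise``,
* ``independent`` — all four hands move on their own latent dynamics,
* ``stillness`` — both dancers nearly motionless; residual micromotion is
  dominated by a small *shared* slow component (settling/tremor transmitted
  through the shared table) plus tiny independent jitter, so joint stillness
  registers as correlated near-zero movement, matching its operational
  status as high coordination.

Speeds are generated directly (all estimators consume speed) and positions
are integrated from them along slowly drifting headings, reflected at the
table bounds, so the coordinate track exactly encodes the scripted speeds.
Likelihoods hover near 0.95 with occasional dropouts below the usual 0.6
cutoff to exercise the conditioning path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EpisodeSpecError
from .moments import MIN_MOMENT_S, Moment
from .pose_io import CANONICAL_MARKERS, MarkerId, PoseTrack

__all__ = ["EpisodeSpec", "SynthSession", "simulate_dyad", "ground_truth_moments"]

#: Table surface size in pixels (square, aerial view).
TABLE_PX = 900.0


@dataclass(frozen=True)
class EpisodeSpec:
    """One scripted episode of dyad dynamics.

    ``lag`` (ms) and ``leader`` apply to coupled episodes only; ``coupling``
    is the follower's mixing weight alpha; ``noise_sd`` scales the latent
    movement speed (px/s).
    """

    start: float
    end: float
    mode: str  # coupled | independent | stillness
    leader: str = "A"
    lag: float = 150.0
    coupling: float = 0.9
    noise_sd: float = 80.0

    def __post_init__(self) -> None:
        if self.mode not in ("coupled", "independent", "stillness"):
            raise EpisodeSpecError(f"unknown episode mode {self.mode!r}")
        if self.end <= self.start:
            raise EpisodeSpecError("episode end must exceed start")
        if self.mode == "coupled":
            if self.leader not in ("A", "B"):
                raise EpisodeSpecError("leader must be 'A' or 'B'")
            if not 50.0 <= self.lag <= 400.0:
                raise EpisodeSpecError(f"lag must lie in [50, 400] ms, got {self.lag}")
        if not 0.0 <= self.coupling <= 1.0:
            raise EpisodeSpecError(f"coupling must lie in [0, 1], got {self.coupling}")


@dataclass
class SynthSession:
    """A simulated session: coordinate track, episode script, seed."""

    track: PoseTrack
    episodes: tuple[EpisodeSpec, ...]
    seed: int
    #: the latent (pre-integration) speed series per marker, for tests
    latent_speeds: dict[MarkerId, np.ndarray] = field(default_factory=dict, repr=False)


def _validate_script(episodes: Sequence[EpisodeSpec], duration: float) -> None:
    prev_end = 0.0
    for ep in episodes:
        if ep.start < prev_end:
            raise EpisodeSpecError(
                f"episodes must be ordered and non-overlapping; episode at "
                f"{ep.start} s starts before {prev_end} s"
            )
        prev_end = ep.end
    if prev_end > duration:
        raise EpisodeSpecError(f"episodes extend past the {duration}-s session")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance."""
    x = np.empty(n)
    x[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - phi * phi)
    eps = rng.normal(size=n - 1) * innov_sd
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _movemean(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def simulate_dyad(
    episodes: Sequence[EpisodeSpec],
    duration: float = 900.0,
    fps: float = 60.0,
    seed: int = 0,
    stillness_jitter_sd: float = 2.0,
    dropout_rate: float = 0.005,
) -> SynthSession:
    """Simulate one dyad session from an episode script.

    Unscripted gaps between episodes behave like ``independent`` episodes.
    The same seed reproduces the coordinate track bit-exactly.
    """
    episodes = tuple(episodes)
    _validate_script(episodes, duration)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fps))
    n = n_frames - 1  # speed samples

    markers = list(CANONICAL_MARKERS)
    # full-length latent movement per hand: slow positive "effort" envelope
    base: dict[MarkerId, np.ndarray] = {}
    own: dict[MarkerId, np.ndarray] = {}
    for m in markers:
        base[m] = np.abs(_ar1(rng, n, 0.9))
        own[m] = np.abs(_ar1(rng, n, 0.9))
    shared_still = np.abs(_movemean(_ar1(rng, n, 0.97), 9))
    jitter = {m: np.abs(rng.normal(size=n)) for m in markers}

    speeds: dict[MarkerId, np.ndarray] = {}
    for m in markers:
        speeds[m] = 80.0 * base[m]  # default independent movement

    def span(ep: EpisodeSpec) -> slice:
        return slice(int(round(ep.start * fps)), min(int(round(ep.end * fps)), n))

    for ep in episodes:
        sl = span(ep)
        if ep.mode == "independent":
            for m in markers:
                speeds[m][sl] = ep.noise_sd * base[m][sl]
        elif ep.mode == "stillness":
            for m in markers:
                speeds[m][sl] = (
                    stillness_jitter_sd * shared_still[sl]
                    + 0.1 * stillness_jitter_sd * jitter[m][sl]
                )
        else:  # coupled
            lag_samples = int(round(ep.lag / 1000.0 * fps))
            follower = "B" if ep.leader == "A" else "A"
            for hand in ("left", "right"):
                lead = MarkerId(ep.leader, hand)
                foll = MarkerId(follower, hand)
                lead_speed = ep.noise_sd * base[lead]
                speeds[lead][sl] = lead_speed[sl]
                delayed = np.roll(lead_speed, lag_samples)
                delayed[:lag_samples] = lead_speed[0]
                speeds[foll][sl] = (
                    ep.coupling * delayed[sl]
                    + (1.0 - ep.coupling) * ep.noise_sd * own[foll][sl]
                )

    # integrate speeds into bounded positions with slowly drifting headings
    dt = 1.0 / fps
    margin = 40.0
    data: dict[MarkerId, np.ndarray] = {}
    for m in markers:
        theta = np.cumsum(rng.normal(scale=0.15, size=n)) + rng.uniform(0, 2 * np.pi)
        pos = np.empty((n_frames, 2))
        pos[0] = rng.uniform(margin + 100, TABLE_PX - margin - 100, size=2)
        step_len = speeds[m] * dt
        dx = step_len * np.cos(theta)
        dy = step_len * np.sin(theta)
        x, y = pos[0]
        for f in range(n):
            sx, sy = dx[f], dy[f]
            if not margin <= x + sx <= TABLE_PX - margin:
                sx = -sx
            if not margin <= y + sy <= TABLE_PX - margin:
                sy = -sy
            x += sx
            y += sy
            pos[f + 1] = (x, y)
        lik = np.clip(0.95 + 0.02 * rng.normal(size=n_frames), 0.0, 1.0)
        drop = rng.random(n_frames) < dropout_rate
        lik[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
        data[m] = np.column_stack([pos[:, 0], pos[:, 1], lik])

    track = PoseTrack(fps=fps, data=data)
    return SynthSession(
        track=track,
        episodes=episodes,
        seed=seed,
        latent_speeds={m: speeds[m].copy() for m in markers},
    )


def ground_truth_moments(session: SynthSession) -> list[Moment]:
    """Episodes of at least 10 s, labelled by their scripted mode.

    Coupled and joint-stillness episodes map to *high* coordination;
    independent episodes map to *low*.
    """
    out = []
    for ep in session.episodes:
        if ep.end - ep.start < MIN_MOMENT_S:
            continue
        label = "low" if ep.mode == "independent" else "high"
        out.append(Moment(start=ep.start, end=ep.end, rated_label=label))
    return out
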
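"""Rated moments, evidence-based high/low classification, and linkage to
participants' own segment annotations.

A *moment* is a rater-identified interval of sustained (>= 10 s) high or low
interpersonal coordination. The classifier compares two areas under the MCV
curve relative to a threshold ``y`` (default 0.5): evidence for high
coordination is the area above ``y``, evidence for low coordination the area
below it; the larger evidence wins. Ties go to *high* — the method favours
over-detection of high coordination so that candidate moments of connection
are not overlooked.

A *segment* is a participant-marked interval between felt transitions in the
interaction, carrying a 1–10 coordination rating, binary perception flags
(perceived role, perceived connection, plus two further selections) and free
commentary. Moments and segments *co-occur* when the moment, expanded by a
tolerance on each side (default 90 s per side, 180 s total), intersects the
segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .errors import InputError, ParseError, UnclassifiableMomentError
from .mcv import MCVSeries

__all__ = [
    "MIN_MOMENT_S",
    "Moment",
    "Segment",
    "ClassifierConfig",
    "Evidence",
    "ConfusionMatrix",
    "BLOCK_SCHEDULE",
    "Condition",
    "evidence",
    "classify_moments",
    "evaluate",
    "evaluate_samples",
    "condition_of",
    "cooccurring",
    "read_moments_csv",
    "read_segments_csv",
]

#: Minimum sustained duration for an interval to count as a moment.
MIN_MOMENT_S = 10.0

Label = Literal["high", "low", "unrated"]


@dataclass(frozen=True)
class Moment:
    """A rated interval of sustained high or low coordination."""

    start: float
    end: float
    rated_label: Label = "unrated"

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_MOMENT_S:
            raise InputError(
                f"moment [{self.start}, {self.end}] shorter than {MIN_MOMENT_S} s"
            )
        if self.rated_label not in ("high", "low", "unrated"):
            raise InputError(f"label must be high/low/unrated, got {self.rated_label!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Segment:
    """A participant-annotated interval between felt transitions."""

    start: float
    end: float
    participant: str
    coordination_rating: int
    role: bool = False
    connection: bool = False
    flag3: bool = False
    flag4: bool = False
    commentary: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(f"segment end {self.end} must exceed start {self.start}")
        if not 1 <= self.coordination_rating <= 10:
            raise InputError(
                f"coordination rating must be in 1..10, got {self.coordination_rating}"
            )
        if self.participant not in ("A", "B"):
            raise InputError(f"participant must be A or B, got {self.participant!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Evidence threshold for the high/low classifier."""

    y: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 < self.y < 1.0:
            raise InputError(f"threshold y must lie in (-1, 1), got {self.y}")


@dataclass(frozen=True)
class Evidence:
    """Areas (correlation x seconds) above/below the classifier threshold."""

    e_high: float
    e_low: float

    @property
    def predicted_label(self) -> str:
        return "high" if self.e_high >= self.e_low else "low"


def evidence(
    mcv: MCVSeries, moment: Moment, cfg: ClassifierConfig = ClassifierConfig()
) -> Evidence:
    """Evidence integrals of the MCV against threshold ``y`` over a moment.

    e_high = sum over defined samples with MCV > y of (MCV - y) * dt, and
    symmetrically for e_low; undefined (NaN) samples are skipped.
    """
    fps = mcv.fps
    i0, i1 = int(round(moment.start * fps)), int(round(moment.end * fps))
    # the speed grid has one sample fewer than the coordinate frames, so a
    # moment ending at the session end may overrun by one sample
    if i0 < 0 or i1 > len(mcv) + 1:
        raise InputError(
            f"moment [{moment.start}, {moment.end}] s outside series span "
            f"[0, {(len(mcv) + 1) / fps}] s"
        )
    i1 = min(i1, len(mcv))
    seg = mcv.values[i0:i1]
    seg = seg[~pd.isna(seg)]
    if seg.size == 0:
        raise UnclassifiableMomentError(
            f"moment [{moment.start}, {moment.end}] s has no defined MCV samples"
        )
    dt = 1.0 / fps
    above = seg[seg > cfg.y]
    below = seg[seg < cfg.y]
    return Evidence(
        e_high=float((above - cfg.y).sum() * dt),
        e_low=float((cfg.y - below).sum() * dt),
    )


def classify_moments(
    mcv: MCVSeries,
    moments: Sequence[Moment],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[Evidence]:
    return [evidence(mcv, m, cfg) for m in moments]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion matrix with *high* as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None


def evaluate(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionMatrix:
    """Moment-level confusion matrix from aligned label lists."""
    if len(predictions) != len(truths):
        raise InputError("prediction and truth lists must align")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        if t == "high":
            tp += p == "high"
            fn += p == "low"
        elif t == "low":
            fp += p == "high"
            tn += p == "low"
        else:
            raise InputError(f"truth label must be high or low, got {t!r}")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_samples(
    mcv: MCVSeries,
    moments: Sequence[Moment],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ConfusionMatrix:
    """Sample-level alternative granularity: every defined MCV sample inside
    a rated moment is classified high iff it exceeds ``y`` and scored
    against the moment's label."""
    fps = mcv.fps
    tp = fp = fn = tn = 0
    for m in moments:
        i0, i1 = int(round(m.start * fps)), int(round(m.end * fps))
        seg = mcv.values[i0:i1]
        seg = seg[~pd.isna(seg)]
        high = int((seg > cfg.y).sum())
        low = seg.size - high
        if m.rated_label == "high":
            tp += high
            fn += low
        elif m.rated_label == "low":
            fp += high
            tn += low
        else:
            raise InputError("sample-level evaluation requires rated moments")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


#: Eyes-open/closed schedule of the five 3-min blocks: (eyes_a, eyes_b).
BLOCK_SCHEDULE: tuple[tuple[str, str], ...] = (
    ("closed", "closed"),  # block 1
    ("open", "open"),      # block 2
    ("open", "closed"),    # block 3
    ("closed", "open"),    # block 4
    ("open", "open"),      # block 5
)


@dataclass(frozen=True)
class Condition:
    block: int
    eyes_a: str
    eyes_b: str


def condition_of(moment: Moment, block_s: float = 180.0) -> Condition:
    """Perceptual condition of the block containing the moment midpoint.

    Blocks are half-open intervals ``[k*block_s, (k+1)*block_s)``; a midpoint
    on a boundary belongs to the later block. Midpoints past the last
    boundary fall in the final block.
    """
    block = min(int(moment.midpoint // block_s), len(BLOCK_SCHEDULE) - 1)
    eyes_a, eyes_b = BLOCK_SCHEDULE[block]
    return Condition(block=block + 1, eyes_a=eyes_a, eyes_b=eyes_b)


def cooccurring(
    moments: Sequence[Moment],
    segments: Sequence[Segment],
    tolerance: float = 90.0,
) -> list[tuple[Moment, Segment]]:
    """Moment/segment pairs whose intervals intersect once the moment is
    expanded by ``tolerance`` seconds on each side (180 s total by default).
    Touching intervals count as intersecting."""
    pairs = []
    for m in moments:
        lo, hi = m.start - tolerance, m.end + tolerance
        for s in segments:
            if lo <= s.end and s.start <= hi:
                pairs.append((m, s))
    return pairs


def read_moments_csv(path: str | Path) -> list[Moment]:
    """Moments CSV: session,start_s,end_s,label (label high/low/unrated).

    Intervals shorter than 10 s are rejected: they do not qualify as
    moments by definition.
    """
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}")
    moments = []
    for _, row in df.iterrows():
        try:
            moments.append(
                Moment(
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    rated_label=str(row["label"]),
                )
            )
        except InputError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return moments


def read_segments_csv(path: str | Path) -> list[Segment]:
    """Segments CSV:
    session,participant,start_s,end_s,rating,role,connection,flag3,flag4,comment."""
    df = pd.read_csv(path)
    required = {"participant", "start_s", "end_s", "rating"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}")
    segments = []
    for _, row in df.iterrows():
        try:
            segments.append(
                Segment(
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    participant=str(row["participant"]),
                    coordination_rating=int(row["rating"]),
                    role=bool(row.get("role", False)),
                    connection=bool(row.get("connection", False)),
                    flag3=bool(row.get("flag3", False)),
                    flag4=bool(row.get("flag4", False)),
                    commentary=str(row.get("comment", "") or ""),
                )
            )
        except InputError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return segments
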
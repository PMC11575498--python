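"""End-to-end orchestration: pose CSV -> conditioned track -> speeds ->
MCV + significance -> moment classification -> NSTE -> co-occurrence report.

Every stage writes a plain-text artifact into the output directory; a run
log records the seed and a hash of the configuration so identical inputs
and config reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

from .config import PipelineConfig, dump_config
from .errors import DyadcoordError
from .kinematics import preprocess, write_speed_csv
from .mcv import mcv_from_speeds, significance_threshold, write_mcv_csv
from .moments import (
    ClassifierConfig,
    classify_moments,
    condition_of,
    cooccurring,
    evaluate,
    read_moments_csv,
    read_segments_csv,
)
from .nste import nste_windowed
from .pose_io import MarkerId, apply_pcutoff, median_filter_track, read_dlc_csv, read_plain_csv

__all__ = ["run_pipeline"]

log = logging.getLogger("dyadcoord")


def _stage(name: str):
    """Wrap stage errors with the stage name for actionable CLI messages."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, DyadcoordError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    pose_path: str | Path,
    out_dir: str | Path,
    moments_path: str | Path | None = None,
    segments_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    pose_format: str = "dlc",
    do_nste: bool = True,
) -> dict:
    """Run the full analysis and return the report dict (also written to
    ``report.json``). A missing moments file skips classification and the
    data-sliding test with a warning; a missing segments file skips the
    co-occurrence report."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = dump_config(cfg)
    (out / "config.yaml").write_text(cfg_text)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    log.info("pipeline start: seed=%s config_hash=%s", cfg.seed, cfg_hash)

    with _stage("pose_io"):
        marker_map = {
            name: MarkerId(*label.split("_")) for name, label in cfg.marker_map.items()
        }
        if pose_format == "dlc":
            track = read_dlc_csv(pose_path, marker_map=marker_map, fps=cfg.fps)
        elif pose_format == "plain":
            track = read_plain_csv(pose_path, fps=cfg.fps)
        else:
            raise DyadcoordError(f"unknown pose format {pose_format!r}")
        track = apply_pcutoff(track, cfg.p_cutoff)
        track = median_filter_track(track, cfg.median_filter_window)

    with _stage("kinematics"):
        speeds = preprocess(
            track,
            cfg.expected_frames,
            outlier_window=cfg.outlier_window,
            outlier_nsd=cfg.outlier_nsd,
            smooth_window=cfg.smooth_window,
        )
        write_speed_csv(speeds, out / "speed.csv", sidecar=out / "outlier_fractions.json")

    with _stage("mcv"):
        cvs, mcv = mcv_from_speeds(speeds, window=cfg.mcv_window)
        write_mcv_csv(cvs, mcv, out / "mcv.csv")

    report: dict = {"seed": cfg.seed, "config_hash": cfg_hash}

    moments = None
    if moments_path is not None and Path(moments_path).exists():
        with _stage("moments"):
            moments = read_moments_csv(moments_path)
    else:
        warnings.warn(
            "no moments file: skipping significance test and classification",
            stacklevel=2,
        )

    if moments:
        with _stage("significance"):
            thresholds = []
            for i, m in enumerate(moments):
                thr = significance_threshold(
                    speeds,
                    m.start,
                    m.end,
                    n_slides=cfg.n_slides,
                    percentile=cfg.slide_percentile,
                    seed=cfg.seed + i,
                    window=cfg.mcv_window,
                    slide_participant=cfg.slide_participant,
                )
                thresholds.append(
                    {
                        "moment": [m.start, m.end],
                        "threshold": thr.threshold,
                        "n_slides": thr.n_slides,
                        "percentile": thr.percentile,
                        "seed": thr.seed,
                    }
                )
            (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))

        with _stage("classify"):
            ccfg = ClassifierConfig(y=cfg.classifier_y)
            evidences = classify_moments(mcv, moments, ccfg)
            rated = [
                (m, e) for m, e in zip(moments, evidences) if m.rated_label != "unrated"
            ]
            per_moment = [
                {
                    "start": m.start,
                    "end": m.end,
                    "rated": m.rated_label,
                    "predicted": e.predicted_label,
                    "e_high": e.e_high,
                    "e_low": e.e_low,
                    "block": condition_of(m).block,
                }
                for m, e in zip(moments, evidences)
            ]
            report["moments"] = per_moment
            if rated:
                cm = evaluate(
                    [e.predicted_label for _, e in rated],
                    [m.rated_label for m, _ in rated],
                )
                report["confusion_matrix"] = {
                    "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                }
                report["metrics"] = {
                    "accuracy": cm.accuracy,
                    "precision": cm.precision,
                    "sensitivity": cm.sensitivity,
                }

    if do_nste:
        with _stage("nste"):
            result = nste_windowed(speeds, cfg.nste)
            result.write_csv(out / "nste.csv")

    if segments_path is not None and Path(segments_path).exists() and moments:
        with _stage("cooccurrence"):
            segments = read_segments_csv(segments_path)
            pairs = cooccurring(moments, segments, tolerance=cfg.cooccurrence_tolerance)
            report["cooccurrences"] = [
                {
                    "moment": [m.start, m.end],
                    "segment": [s.start, s.end],
                    "participant": s.participant,
                    "rating": s.coordination_rating,
                }
                for m, s in pairs
            ]

    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline done: artifacts in %s", out)
    return report
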
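"""Pipeline configuration.

Defaults reproduce the study conditions end to end: 60 Hz video, 15-min
sessions (54,000 frames), likelihood cutoff 0.6, 5-frame coordinate median
filter, 1-s/3-SD outlier removal, 0.5-s speed smoothing, 5-s correlation
windows, classifier threshold y = 0.5, 1,000 data slides at the 95th
percentile, NSTE with m = 3 / 2-s windows / 0.5-s steps / tau 6..15
samples, and a 90-s-per-side moment/segment co-occurrence tolerance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .nste import NSTEParams

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    fps: float = 60.0
    expected_frames: int = 54_000
    p_cutoff: float = 0.6
    median_filter_window: int = 5            # frames
    outlier_window: float = 1.0              # s
    outlier_nsd: float = 3.0
    smooth_window: float = 0.5               # s
    mcv_window: float = 5.0                  # s
    classifier_y: float = 0.5
    n_slides: int = 1000
    slide_percentile: float = 95.0
    slide_participant: str = "A"
    seed: int = 0
    nste: NSTEParams = field(default_factory=NSTEParams)
    cooccurrence_tolerance: float = 90.0     # s per side
    #: body-part name -> "participant_hand" marker label
    marker_map: dict[str, str] = field(
        default_factory=lambda: {
            "A_left": "A_left",
            "A_right": "A_right",
            "B_left": "B_left",
            "B_right": "B_right",
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nste"] = asdict(self.nste)
        d["nste"]["tau_range"] = list(self.nste.tau_range)
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing keys keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    nste_raw = raw.pop("nste", {})
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"{path}: unknown config key {key!r}")
        setattr(cfg, key, value)
    if nste_raw:
        d = asdict(cfg.nste)
        for key, value in nste_raw.items():
            if key not in d:
                raise ConfigError(f"{path}: unknown nste key {key!r}")
            d[key] = value
        d["tau_range"] = tuple(d["tau_range"])
        cfg.nste = NSTEParams(**d)
    return cfg


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)
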
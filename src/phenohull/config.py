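"""Pipeline configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hull import DEFAULT_SIMPLIFY_TOL
from .planttype import TypeIntervals
from .preprocess import DEFAULT_BLACK_MIN_RGB, StatFilterParams
from .projection import DEFAULT_STEP_DEG, DEFAULT_TARGET_HEIGHT

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of the classification pipeline.

    Mirrors the stage order: statistical filter -> color filter -> voxel
    down-sample -> projection/normalization -> hull simplification ->
    interval classification.  ``voxel_leaf=None`` means 2% of the
    bounding-box diagonal.
    """

    stat_filter: StatFilterParams = field(default_factory=StatFilterParams)
    color_min_rgb: tuple[int, int, int] = DEFAULT_BLACK_MIN_RGB
    color_max_rgb: tuple[int, int, int] = (255, 255, 255)
    voxel_leaf: float | None = None
    step_deg: float = DEFAULT_STEP_DEG
    target_height: float = DEFAULT_TARGET_HEIGHT
    simplify_tol: float = DEFAULT_SIMPLIFY_TOL
    intervals: TypeIntervals = field(default_factory=TypeIntervals)
    out_dir: Path = Path("phenohull_out")


_SCHEMA = {
    "stat_filter": {"k", "std_mult"},
    "color_filter": {"min_rgb", "max_rgb"},
    "voxel": {"leaf"},
    "projection": {"step_deg", "target_height"},
    "hull": {"simplify_tol"},
    "intervals": {"cylinder", "tower"},
    "out_dir": None,
}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys at either nesting level are rejected so typos fail loudly.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for section, value in raw.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        allowed = _SCHEMA[section]
        if allowed is None:
            setattr(cfg, "out_dir", Path(value))
            continue
        if not isinstance(value, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key in value:
            if key not in allowed:
                raise ValueError(f"unknown config key {section}.{key}")
        if section == "stat_filter":
            cfg.stat_filter = StatFilterParams(
                k=int(value.get("k", cfg.stat_filter.k)),
                std_mult=float(
                    value.get("std_mult", cfg.stat_filter.std_mult)
                ),
            )
        elif section == "color_filter":
            if "min_rgb" in value:
                cfg.color_min_rgb = tuple(value["min_rgb"])
            if "max_rgb" in value:
                cfg.color_max_rgb = tuple(value["max_rgb"])
        elif section == "voxel":
            leaf = value.get("leaf")
            cfg.voxel_leaf = None if leaf is None else float(leaf)
        elif section == "projection":
            cfg.step_deg = float(value.get("step_deg", cfg.step_deg))
            cfg.target_height = float(
                value.get("target_height", cfg.target_height)
            )
        elif section == "hull":
            cfg.simplify_tol = float(
                value.get("simplify_tol", cfg.simplify_tol)
            )
        elif section == "intervals":
            cfg.intervals = TypeIntervals(
                cylinder=tuple(
                    value.get("cylinder", cfg.intervals.cylinder)
                ),
                tower=tuple(value.get("tower", cfg.intervals.tower)),
            )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config override {key!r}")
        setattr(cfg, key, val)
    return cfg
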
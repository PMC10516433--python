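"""Run configuration: one nested tree of defaults, merged with a YAML file.

Unknown keys are rejected so typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml
from scipy.stats import chi2

from .association import TrackerConfig

__all__ = ["DEFAULTS", "load_config", "tracker_config_from"]

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "motion": {
        # noise std = weight * box height (px)
        "std_weight_position": 1.0 / 20,
        "std_weight_velocity": 1.0 / 160,
        # motion gate: chi-squared quantile of the 4-dim measurement
        "gating_chi2_quantile": 0.95,
    },
    "appearance": {
        "dim": 128,
        "gate": 0.25,  # max admissible cosine matching degree
    },
    "tracker": {
        "ct": 0.0,       # detector confidence threshold (set per detector)
        "n_init": 3,
        "max_age": 100,  # appearance kept over 100 frames for occlusion recovery
        "iou_gate": 0.3,
    },
    "matcher": {
        "threshold_px": 8.0,
        "outlier_fraction": 0.1,
        "min_overlap": 10,
    },
    "reconstruction": {
        "max_gap": 10,
    },
    "metrics": {
        "iou_threshold": 0.5,
        "motp_as_distance": False,
    },
    "scene": {
        "n_bees": 3,
        "n_frames": 300,
        "tunnel": [2000.0, 300.0, 300.0],
        "speed_scale": 8.0,
        "turn_rate": 0.02,
        "damping": 0.1,
    },
    "noise": {
        "jitter_px": 1.0,
        "miss_rate": 0.02,
        "clutter_rate": 0.2,
        "descriptor_angle_deg": 5.0,
        "descriptor_separation_deg": 60.0,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"{here}: expected a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with ``overrides``."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, doc)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def tracker_config_from(cfg: dict) -> TrackerConfig:
    return TrackerConfig(
        ct=cfg["tracker"]["ct"],
        n_init=cfg["tracker"]["n_init"],
        max_age=cfg["tracker"]["max_age"],
        iou_gate=cfg["tracker"]["iou_gate"],
        appearance_gate=cfg["appearance"]["gate"],
        motion_gate=float(chi2.ppf(cfg["motion"]["gating_chi2_quantile"], df=4)),
        std_weight_position=cfg["motion"]["std_weight_position"],
        std_weight_velocity=cfg["motion"]["std_weight_velocity"],
    )
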
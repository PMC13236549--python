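"""Experiment configuration: one YAML file with documented defaults.

Any omitted value falls back to the default below; the fully resolved
configuration is written verbatim into the run directory so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["ConfigError", "load_config", "resolve_config", "write_config",
           "DEFAULTS"]


class ConfigError(ValueError):
    """Raised for malformed configuration files (maps to exit code 2)."""


DEFAULTS: dict = {
    "seed": 0,
    "phantom": {
        "preset": "easy",          # easy | decoy | default
        "shape": [48, 48, 48],
        "n_cases": 25,
        "train_fraction": 0.8,
    },
    "ssl": {
        "epochs": 5,
        "patch_size": 32,
        "batch_size": 2,
        "patches_per_case": 4,
        "learning_rate": 1.0e-4,
        "temperature": 0.05,
        "use_organ_channel": False,
    },
    "detector": {
        "encoder": "cnn_unet",     # cnn_unet | swin
        "use_organ_channel": False,
        "epochs": 6,
        "iterations_per_epoch": 25,
        "batch_size": 2,
        "patch_size": 48,
        "learning_rate": 0.01,
        "warmup_iterations": 20,
        "fpn_width": 16,
    },
    "inference": {
        "nms_iou": 0.3,
        "min_confidence": 0.05,
        "min_object_size": 0.0,
        "max_detections": 100,
    },
    "evaluation": {
        "iou_set": [0.1, 0.2, 0.3, 0.4, 0.5],
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration field '{where}'")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"field '{where}' must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def resolve_config(overrides: dict | None) -> dict:
    return _merge(DEFAULTS, overrides or {})


def load_config(path=None) -> dict:
    """Read a YAML config and resolve it against the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {p}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return resolve_config(raw)


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
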
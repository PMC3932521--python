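"""Run configuration: a flat YAML key-value document, strictly validated.

Unknown keys are rejected; every stochastic stage requires an explicit
seed; paths are resolved before any stage runs.
"""

from __future__ import annotations

import os
from pathlib import Path

import yaml

__all__ = ["load_config", "validate_config", "ConfigError", "STAGE_KEYS"]


class ConfigError(ValueError):
    pass


_COMMON = {"out_dir", "log_level"}

STAGE_KEYS: dict[str, dict] = {
    "simulate": dict(
        required={"seed"},
        optional={"preset", "twist", "rise", "n_start", "n_filaments", "length",
                  "box", "overlap", "snr", "noise_sigma", "pixel", "radius",
                  "template", "defocus_um", "stack_out"},
        stochastic=True,
    ),
    "index": dict(
        required={"stack"},
        optional={"filament_radius", "max_order", "diameter"},
        stochastic=False,
    ),
    "refine": dict(
        required={"stack"},
        optional={"init_twist", "init_rise", "n_start", "max_iters",
                  "cylinder_diameter", "tol_twist", "tol_rise",
                  "azimuth_step", "tilt_range", "tilt_step", "volume_out"},
        stochastic=False,
    ),
    "validate": dict(
        required={"stack"},
        optional={"init_twist", "init_rise", "n_start", "max_iters", "threshold",
                  "mode"},
        stochastic=False,
    ),
    "dock": dict(
        required={"map"},
        optional={"template", "coarse_step", "fine_step", "nominal_hand",
                  "init_radius"},
        stochastic=False,
    ),
    "quant": dict(
        required={"seed"},
        optional={"n", "mean", "sd", "min_len", "bin_width", "twist", "rise", "n_start"},
        stochastic=True,
    ),
}

_PATH_KEYS = {"stack", "map", "template", "stack_out", "volume_out", "out_dir"}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    return cfg


def validate_config(cfg: dict, stage: str, base_dir: str = ".") -> dict:
    """Validate a config for a stage; returns a copy with paths resolved."""
    if stage not in STAGE_KEYS:
        raise ConfigError(f"unknown stage {stage!r}")
    spec = STAGE_KEYS[stage]
    known = spec["required"] | spec["optional"] | _COMMON
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys for {stage}: {sorted(unknown)}")
    missing = spec["required"] - set(cfg)
    if missing:
        raise ConfigError(f"missing required keys for {stage}: {sorted(missing)}")
    if spec["stochastic"] and not isinstance(cfg.get("seed"), int):
        raise ConfigError(f"stage {stage} requires an integer seed")
    out = dict(cfg)
    for k in _PATH_KEYS & set(out):
        if isinstance(out[k], str):
            p = Path(base_dir) / out[k] if not os.path.isabs(out[k]) else Path(out[k])
            out[k] = str(p)
            if k in {"stack", "map"} and not p.exists():
                raise ConfigError(f"{k}: file not found: {p}")
    return out
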
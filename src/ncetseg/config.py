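"""Run configuration: defaults, YAML loading and deep-merging.

One global ``seed`` feeds every stochastic component (phantom generation,
mixture initialization, proportional imputation). Each pipeline stage owns a
block: ``nlsvfmm``, ``cleanup``, ``validation``, ``survival``, ``phantom``.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "nlsvfmm": {
        "patch_radius": 1,
        "search_radius": 2,
        "bandwidth": None,
        "beta": 1.0,
        "max_iter": 100,
        "tol": 1e-5,
        "mixing_mode": "nonlocal_spatially_varying",
        "variance_floor": 1e-6,
    },
    "cleanup": {
        "enabled": True,
        "band_width_mm": 4.0,
        "min_island_voxels": 100,
        "cet_distance_gate_mm": 10.0,
        "gate_scope": "component",
    },
    "validation": {
        "alpha": 0.01,
        "delta_i_cutoff": 5.0,
        "summary": "mean",
    },
    "survival": {
        "impute": "modal",
        "tier": "full",
        "include_tfhi": True,
    },
    "phantom": {},
}


def deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = deep_merge(cfg, user)
    if overrides:
        cfg = deep_merge(cfg, overrides)
    return cfg
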
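"""Run configuration: YAML in, validated dict out.

A deliberately small schema: every key is optional with the package
defaults, unknown keys are rejected so typos fail loudly before a long run.
"""
from __future__ import annotations

import yaml

from .errors import ParameterError

_SCHEMA: dict[str, tuple[type, ...]] = {
    # io / tiling
    "target_size": (int,),
    "tile_size": (int,),
    "overlap": (int,),
    "enhancement": (bool,),
    # detection
    "radius_min": (int, float),
    "radius_max": (int, float),
    "sensitivity": (int, float),
    "min_separation": (int, float),
    "contrast_channel": (str,),
    "edge_threshold": (int, float),
    # classification
    "model_path": (str,),
    # scoring
    "deletion_threshold": (int, float),
    "amplification_threshold": (int, float),
    "direction": (str,),
    "mixed_policy": (str,),
    # heterogeneity
    "n_random": (int,),
    "radius": (int, float),
    "k_max": (int,),
    # misc
    "seed": (int,),
    "out_dir": (str,),
}

DEFAULTS: dict = {
    "target_size": 4096,
    "tile_size": 4096,
    "overlap": 64,
    "enhancement": False,
    "mixed_policy": "count_both",
    "direction": "deletion_assay",
    "deletion_threshold": 0.60,
    "amplification_threshold": 2.0,
    "n_random": 300,
    "radius": 60.0,
    "k_max": 5,
    "seed": 0,
}


def validate_config(cfg: dict) -> dict:
    """Schema-check a raw mapping; returns defaults overlaid with ``cfg``."""
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a mapping")
    out = dict(DEFAULTS)
    for key, value in cfg.items():
        if key not in _SCHEMA:
            raise ParameterError(f"unknown config key {key!r}")
        types = _SCHEMA[key]
        if not isinstance(value, types) or isinstance(value, bool) and bool not in types:
            raise ParameterError(
                f"config key {key!r} expects {'/'.join(t.__name__ for t in types)}, "
                f"got {type(value).__name__}"
            )
        out[key] = value
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
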
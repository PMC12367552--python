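"""Run configuration: YAML-backed, versioned, with paper-faithful defaults.

Every module-level numerical decision (the environmental-composite epsilon,
the percentile convention, quantile boundary closure, normalization pools,
the robust-SE variant) is visible here so a run is fully described by its
config plus a seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "config_hash", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1

_DEFAULTS: dict = {
    "schema_version": CONFIG_SCHEMA_VERSION,
    "seed": 0,
    "world": {},  # overrides for synthetic.WorldConfig fields
    "catalog": {
        "sensitivity_remap": False,  # move water/waste into economic/social
        "overrides": {},  # per-type category overrides
    },
    "calibration": {
        "enabled": True,
        "per_category": False,  # one shared (a, b) fit by default
    },
    "env": {
        "epsilon": 1.0e-6,  # floor on the Air + Heat denominator
    },
    "exposure": {
        "percentile": 95.0,  # normalization percentile (linear interpolation)
        "treat_missing_as_zero": False,
        "levels": ["country", "county"],
    },
    "classification": {
        "lower_q": 25.0,
        "upper_q": 75.0,  # threshold values themselves class as M
    },
    "health": {
        "log_transform": "auto",  # log response only when KS rejects normality
        "group_as_fixed": False,  # fallback replacing the 2-group random intercept
        "rf_runs": 100,
        "rf_trees": 500,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with a YAML override file (if given)."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        version = override.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {version} != supported {CONFIG_SCHEMA_VERSION}"
            )
        config = _merge(config, override)
    _validate(config)
    return config


def _validate(config: dict) -> None:
    if not 0 < config["exposure"]["percentile"] <= 100:
        raise ValueError("exposure.percentile must be in (0, 100]")
    lo, hi = config["classification"]["lower_q"], config["classification"]["upper_q"]
    if not 0 <= lo < hi <= 100:
        raise ValueError("classification quantiles must satisfy 0 <= lower < upper <= 100")
    if config["env"]["epsilon"] <= 0:
        raise ValueError("env.epsilon must be > 0")
    lt = config["health"]["log_transform"]
    if lt not in ("auto", True, False):
        raise ValueError("health.log_transform must be 'auto', true or false")


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
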
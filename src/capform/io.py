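"""Configuration files and tabular export.

Parameter sets round-trip through a flat key-value YAML file whose keys are
exactly the ``ModelParams`` field names plus ``epsilon`` and ``profile_m``.
An optional ``presets`` section maps names to full parameter sets of the
same shape.  Field tables are written as CSV with 12 significant digits
(stable regression fixtures that remain human-readable) next to a JSON
manifest recording parameters and truncation data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .model import InitialProfile, ModelParams, PerturbationConfig, make_bump_profile

__all__ = [
    "CSV_FLOAT_FORMAT",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_fields_csv",
    "write_manifest",
]

CSV_FLOAT_FORMAT = "%.12g"

_PARAM_FIELDS = [f.name for f in dataclasses.fields(ModelParams)]


def config_to_dict(
    params: ModelParams, epsilon: float, profile_m: int
) -> dict[str, Any]:
    d = {name: getattr(params, name) for name in _PARAM_FIELDS}
    d["epsilon"] = epsilon
    d["profile_m"] = profile_m
    return d


def config_from_dict(d: dict[str, Any]) -> tuple[ModelParams, PerturbationConfig]:
    """Build (params, perturbation config) from a flat key-value mapping."""
    unknown = set(d) - set(_PARAM_FIELDS) - {"epsilon", "profile_m", "presets"}
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParams(**{k: float(d[k]) for k in _PARAM_FIELDS if k in d})
    epsilon = float(d.get("epsilon", 0.05))
    theta = make_bump_profile(int(d.get("profile_m", 2)))
    return params, PerturbationConfig.from_params(epsilon, theta, params)


def load_config(
    path: str | Path, preset: str | None = None
) -> tuple[ModelParams, PerturbationConfig]:
    """Read a YAML config; ``preset`` selects an entry of its presets section."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if preset is not None:
        presets = raw.get("presets", {})
        if preset not in presets:
            raise KeyError(
                f"preset {preset!r} not in config file; available: "
                f"{sorted(presets)}"
            )
        raw = presets[preset]
    return config_from_dict(raw)


def save_config(
    path: str | Path, params: ModelParams, epsilon: float, profile_m: int
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(params, epsilon, profile_m), fh, sort_keys=False)


def write_fields_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_manifest(path: str | Path, payload: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
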
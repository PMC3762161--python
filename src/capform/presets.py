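"""Named parameter presets and reference-table generation.

The worked example of the model uses ``epsilon = 0.05``, ``lambda = 20``,
``mu = 5``, ``beta = 10``, ``K = 0.1``, ``D_eta = 0.25`` with the quartic
bump ``theta(y) = 30 y^2 (1-y)^2``.  The lumped constant ``K`` does not pin
down the individual transition constants, so the presets carry a
"compatible" full parameter set (alpha1=0.1, alpha2=10, beta1=2, beta2=0.5,
gamma2=1, gamma1 calibrated) whose derived ``K`` equals 0.1 exactly; the
closed-form route only ever consumes ``K`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic import assemble_fields, fourier_spectrum
from .model import (
    InitialProfile,
    ModelParams,
    PerturbationConfig,
    calibrate_exponents,
    make_bump_profile,
)
from .numeric import Grid

__all__ = ["Preset", "load_preset", "available_presets", "reference_tables"]

EXAMPLE_K = 0.1


@dataclass(frozen=True)
class Preset:
    """A named, fully specified model configuration."""

    name: str
    config: PerturbationConfig
    params: ModelParams | None
    notes: str


def _compatible_params() -> ModelParams:
    base = ModelParams(
        lambda_=20.0,
        nu=1.0,
        beta=10.0,
        mu=5.0,
        D_eta=0.25,
        eta0=1.0,
        f0=1.0,
        alpha1=0.1,
        alpha2=10.0,
        beta1=2.0,
        beta2=0.5,
        gamma1=1.0,
        gamma2=1.0,
    )
    return calibrate_exponents(base, EXAMPLE_K)


def _build(name: str) -> Preset:
    params = _compatible_params()
    if name == "example2013":
        theta = make_bump_profile(2)
        return Preset(
            name=name,
            config=PerturbationConfig.from_params(0.05, theta, params),
            params=params,
            notes="worked example: quartic bump, eps=0.05, K=0.1, D_eta=0.25",
        )
    if name == "rest":
        theta = make_bump_profile(2)
        return Preset(
            name=name,
            config=PerturbationConfig.from_params(0.0, theta, params),
            params=params,
            notes="unperturbed rest state (eps=0): all fields stay constant",
        )
    if name == "example2013-m3":
        theta = make_bump_profile(3)
        return Preset(
            name=name,
            config=PerturbationConfig.from_params(0.05, theta, params),
            params=params,
            notes="sharper bump m=3 (A=140), otherwise the worked-example constants",
        )
    raise KeyError(
        f"unknown preset {name!r}; available: {', '.join(available_presets())}"
    )


def available_presets() -> list[str]:
    return ["example2013", "rest", "example2013-m3"]


def load_preset(name: str) -> Preset:
    """Return the named preset; raises ``KeyError`` listing the registry."""
    return _build(name)


def reference_tables(
    preset: Preset,
    grid: Grid | None = None,
    times: Sequence[float] = (0.0, 0.05, 0.1),
    N: int = 200,
) -> pd.DataFrame:
    """Frozen analytic-field table used as a regression fixture.

    Pure deterministic arithmetic: regeneration is bit-stable across runs on
    the same platform.  Columns (y, t, v, c, f, eta), one row per node and
    time.
    """
    if grid is None:
        grid = Grid(101)
    y = grid.y
    params = preset.params if preset.params is not None else ModelParams()
    spectrum = fourier_spectrum(preset.config.theta, preset.config.K, N=N)
    rows = []
    for t in times:
        fields = assemble_fields(
            y, t, preset.config, params=params, spectrum=spectrum
        )
        rows.append(
            pd.DataFrame(
                {
                    "y": y,
                    "t": np.full_like(y, t),
                    "v": fields.v,
                    "c": fields.c,
                    "f": fields.f,
                    "eta": fields.eta,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
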
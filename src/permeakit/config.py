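"""Structured (YAML) configuration for simulations and analyses.

Recipes are plain key-value trees so that every fixture trajectory is
regenerable from one file.  The builders here turn dictionaries into the
spec objects of :mod:`permeakit.bd`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import bd


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def build_potential(spec: Mapping[str, Any]):
    form = spec.get("form")
    if form == "flat":
        return bd.FlatPotential()
    if form == "gaussian_barrier":
        return bd.GaussianBarrier(height=float(spec["height"]),
                                  center=float(spec.get("center", 0.0)),
                                  width=float(spec.get("width", 2.5)))
    if form == "tabulated":
        return bd.TabulatedPotential(spec["z_grid"], spec["w"])
    raise ConfigError(f"unknown potential form {form!r}")


def build_diffusion(spec: Mapping[str, Any]):
    form = spec.get("form", "constant")
    if form == "constant":
        return bd.ConstantDiffusion(float(spec["D"]))
    if form == "tabulated":
        return bd.TabulatedDiffusion(spec["z_grid"], spec["D"])
    raise ConfigError(f"unknown diffusion form {form!r}")


def build_bias(spec: Mapping[str, Any]):
    kind = spec.get("kind")
    if kind == "harmonic":
        return bd.HarmonicBias(k=float(spec["k"]), center=float(spec["center"]))
    if kind == "flat_bottom":
        return bd.FlatBottomBias(k=float(spec["k"]), lower=float(spec["lower"]),
                                 upper=float(spec["upper"]))
    if kind == "constant_force":
        return bd.ConstantForceBias(f=float(spec["f"]))
    raise ConfigError(f"unknown bias kind {kind!r}")


def build_biases(specs: Sequence[Mapping[str, Any]] | None):
    return [build_bias(s) for s in (specs or [])]


def build_sim_config(spec: Mapping[str, Any], seed: int | None = None) -> bd.SimConfig:
    kwargs = dict(spec)
    if seed is not None:
        kwargs["seed"] = seed
    for key in ("domain", "absorbing_bounds"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    try:
        return bd.SimConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad simulation config: {exc}") from None


def require_paths(cfg: Mapping[str, Any], keys: Sequence[str]) -> None:
    """Validate that every referenced path exists; name the offending key."""
    for key in keys:
        p = cfg.get(key)
        if p is None or not Path(p).exists():
            raise ConfigError(f"config key {key!r}: path {p!r} does not exist")
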
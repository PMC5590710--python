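"""Configuration loading and validation (YAML/JSON).

A config file carries the population parameters, the effect specification,
and the trial-design defaults.  The packaged ``adni_mci.yaml`` holds the
MCI reference values used throughout the documentation.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import EffectSpec, PopulationParams, TrialDesign

__all__ = [
    "load_config",
    "load_default_config",
    "default_config_path",
    "save_config",
    "config_dict",
]

_DESIGN_DEFAULTS = dict(
    visit_interval_years=0.5,
    allocation=0.5,
    alpha=0.05,
    target_power=0.80,
    sidedness="two_sided_chi2",
)


def default_config_path() -> Path:
    """Path of the packaged MCI reference configuration."""
    return Path(resources.files("mlmm_power").joinpath("data/adni_mci.yaml"))


def _fail(path: str, message: str):
    raise ValueError(f"config error at '{path}': {message}")


def _parse(doc: dict, source: str):
    if not isinstance(doc, dict):
        _fail(source, "top level must be a mapping")
    for key in ("beta2", "sigma_b", "sigma_eps"):
        if key not in doc:
            _fail(key, "missing required key")
    try:
        params = PopulationParams(
            beta2=np.asarray(doc["beta2"], dtype=float),
            sigma_b=np.asarray(doc["sigma_b"], dtype=float),
            sigma_eps=np.asarray(doc["sigma_eps"], dtype=float),
            beta0=np.asarray(doc["beta0"], dtype=float) if "beta0" in doc else None,
            labels=tuple(doc["labels"]) if "labels" in doc else None,
        )
    except ValueError as exc:
        _fail("population parameters", str(exc))
    eff = doc.get("effect", {}) or {}
    try:
        if eff.get("mode", "fraction_of_rate") == "explicit":
            effect = EffectSpec(mode="explicit", gamma_star=np.asarray(eff["gamma_star"], dtype=float))
        else:
            effect = EffectSpec(
                mode="fraction_of_rate",
                reduction_fraction=float(eff.get("reduction_fraction", 0.25)),
            )
    except (KeyError, ValueError) as exc:
        _fail("effect", str(exc))
    des = dict(_DESIGN_DEFAULTS)
    des.update(doc.get("design", {}) or {})
    if "duration_years" not in des:
        _fail("design.duration_years", "missing required key")
    try:
        design = TrialDesign(**des)
    except (TypeError, ValueError) as exc:
        _fail("design", str(exc))
    return params, effect, design


def load_config(path) -> tuple:
    """Read a YAML/JSON config; returns (params, effect, design)."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _parse(doc, str(path))


def load_default_config() -> tuple:
    """The packaged MCI reference configuration."""
    return load_config(default_config_path())


def config_dict(
    params: PopulationParams, effect: EffectSpec, design: TrialDesign
) -> dict:
    """Round-trippable plain-dict form of a configuration."""
    doc = {
        "labels": list(params.labels),
        "beta2": [float(x) for x in params.beta2],
        "sigma_eps": [[float(x) for x in row] for row in params.sigma_eps],
        "sigma_b": [[float(x) for x in row] for row in params.sigma_b],
    }
    if np.any(params.beta0):
        doc["beta0"] = [float(x) for x in params.beta0]
    if effect.mode == "explicit":
        doc["effect"] = {
            "mode": "explicit",
            "gamma_star": [float(x) for x in effect.gamma_star],
        }
    else:
        doc["effect"] = {
            "mode": "fraction_of_rate",
            "reduction_fraction": float(effect.reduction_fraction),
        }
    doc["design"] = {
        "duration_years": float(design.duration_years),
        "visit_interval_years": float(design.visit_interval_years),
        "allocation": float(design.allocation),
        "alpha": float(design.alpha),
        "target_power": float(design.target_power),
        "sidedness": design.sidedness,
    }
    return doc


def save_config(
    params: PopulationParams, effect: EffectSpec, design: TrialDesign, path
) -> None:
    """Write a configuration as YAML (or JSON by extension)."""
    doc = config_dict(params, effect, design)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
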
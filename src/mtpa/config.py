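"""Configuration loading and validation.

A run is fully specified by one YAML file with nested sections
(physiology, drug_defaults, sampling, solver, steady_state, labels, ml).
The packaged defaults describe a 70 kg human and an IgG-like antibody;
any user file is merged over the defaults section by section.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "config_hash"]

_REQUIRED_SECTIONS = (
    "physiology",
    "drug_defaults",
    "sampling",
    "solver",
    "steady_state",
    "labels",
    "ml",
)

_PHYSIOLOGY_KEYS = (
    "v_plasma", "v_tight", "v_leaky", "v_lymph",
    "l_tight", "l_leaky",
    "sigma_tight", "sigma_leaky", "sigma_lymph",
    "cl_plasma", "cl_up_tight", "cl_up_leaky",
    "bw", "charge_cl_coeff", "charge_up_coeff",
)


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


def default_config() -> dict[str, Any]:
    """Return the packaged default configuration as a nested dict."""
    text = (
        importlib.resources.files("mtpa.data")
        .joinpath("default_config.yaml")
        .read_text()
    )
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def load_config(path: str | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load a config file merged over the packaged defaults.

    Parameters
    ----------
    path
        YAML file; ``None`` uses the defaults unchanged.
    overrides
        Flat ``{"section.key": value}`` entries applied last (CLI sweeps).
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path!r} is not a mapping")
        for section, values in user.items():
            if section not in _REQUIRED_SECTIONS:
                raise ConfigError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            cfg[section].update(values)
    if overrides:
        for dotted, value in overrides.items():
            section, _, key = dotted.partition(".")
            if not key or section not in cfg:
                raise ConfigError(f"bad override key {dotted!r}")
            cfg[section][key] = value
    validate_config(cfg)
    return cfg


def validate_config(cfg: Any) -> None:
    """Schema-check a config dict; raise ConfigError naming the problem key."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for section in _REQUIRED_SECTIONS:
        if section not in cfg:
            raise ConfigError(f"missing config section {section!r}")
    phys = cfg["physiology"]
    for key in _PHYSIOLOGY_KEYS:
        if key not in phys:
            raise ConfigError(f"missing physiology key {key!r}")
    for key in ("v_plasma", "v_tight", "v_leaky", "v_lymph",
                "l_tight", "l_leaky", "cl_plasma", "bw"):
        if not phys[key] > 0:
            raise ConfigError(f"physiology.{key} must be > 0")
    for key in ("sigma_tight", "sigma_leaky", "sigma_lymph"):
        if not 0 <= phys[key] < 1:
            raise ConfigError(f"physiology.{key} must be in [0, 1)")
    for key in ("cl_up_tight", "cl_up_leaky"):
        if phys[key] < 0:
            raise ConfigError(f"physiology.{key} must be >= 0")
    drug = cfg["drug_defaults"]
    for key in ("mw", "kon"):
        if key not in drug or not drug[key] > 0:
            raise ConfigError(f"drug_defaults.{key} must be > 0")
    for axis in ("kd", "t0", "t_half"):
        rng = cfg["sampling"].get(axis)
        if (not isinstance(rng, (list, tuple)) or len(rng) != 2
                or not 0 < rng[0] < rng[1]):
            raise ConfigError(f"sampling.{axis} must be [lo, hi] with 0 < lo < hi")
    ss = cfg["steady_state"]
    for key in ("trough_rtol", "max_intervals", "bolus_horizon_days"):
        if key not in ss or not ss[key] > 0:
            raise ConfigError(f"steady_state.{key} must be > 0")


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a config dict (manifest provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def merged(cfg: Mapping[str, Any], **sections: Mapping[str, Any]) -> dict:
    """Return a deep copy of *cfg* with the given sections updated."""
    out = copy.deepcopy(dict(cfg))
    for name, values in sections.items():
        out[name].update(values)
    return out
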
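"""Run configuration: schema, defaults, validation, resolution.

Every computation reachable from the command line goes through a validated
:class:`RunConfig`; CLI flags compile into one, and each run writes its
fully resolved configuration next to its outputs so results are
reconstructible from the output directory alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config", "resolve", "DEFAULTS"]

#: Full schema with defaults. ``None`` marks "no value" (e.g. optional
#: overrides); the parameter file path is the only required entry.
DEFAULTS: dict[str, Any] = {
    "params": None,                 # path to the parameter YAML (required)
    "out_dir": "runs",
    "seed": 0,
    "hill_orientation": "repressive",
    "solver": {
        "rtol": 1e-6,
        "atol": 1e-9,
        "grid_step": 0.01,
    },
    "condition": {
        "s": 1.5,
        "M_override": None,
        "horizon": 24.0,
        "label": "",
    },
    "sweep": {
        "s_low": 1.0,
        "n": 10,
        "span": 4.0,
        "horizon": 24.0,
    },
    "ensemble": {
        "n_reps": 20,
        "noise_amplitude": 0.001,
        "noise_mode": "additive",
    },
    "grid": {
        "m_factors": [1.0, 2.0, 3.0, 4.0],
    },
    "calibrate": {
        "anchors": None,            # path to anchors YAML; None = built-in
        "budget": 200,
        "n_reps": 5,
    },
    "sampling_times": [0.0, 3.0, 6.0, 24.0],
}


class ConfigError(ValueError):
    """Configuration does not validate against the schema."""


def _merge(defaults: Mapping, user: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, validated configuration."""

    data: Mapping[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def to_dict(self) -> dict:
        return copy.deepcopy(dict(self.data))

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RunConfig) and dict(self.data) == dict(
            other.data)


def resolve(user: Mapping[str, Any] | None = None) -> RunConfig:
    """Apply defaults and validate a partial configuration mapping."""
    merged = _merge(DEFAULTS, user or {})
    hill = merged["hill_orientation"]
    if hill not in ("repressive", "saturating"):
        raise ConfigError(
            f"hill_orientation must be 'repressive' or 'saturating', "
            f"got {hill!r}")
    for key in ("rtol", "atol", "grid_step"):
        if merged["solver"][key] <= 0:
            raise ConfigError(f"solver.{key} must be positive")
    return RunConfig(merged)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve(raw)
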
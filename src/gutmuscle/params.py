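"""The dimensionless kinetic constants of the gut-muscle axis model.

The model has 37 strictly positive parameters:

* ``a1..a8``   basal production rates, one per species;
* ``c1``       stimulus gain of the exercise input on SCFA production;
* ``c2..c7``   mass-action interaction rates (positive feedbacks);
* ``d1..d8``   first-order degradation rates, one per species;
* ``l1..l6``   Hill-coupled repression strengths (negative feedbacks);
* ``K1..K6``   Hill half-saturation constants paired with ``l1..l6``;
* ``K``        half-saturation of the exercise stimulus;
* ``M``        delay coefficient scaling intensity-dependent AKT degradation.

All quantities are dimensionless; one model time unit is one hour.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = ["PARAM_NAMES", "ParameterSet"]

PARAM_NAMES: tuple[str, ...] = (
    "a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8",
    "c1", "c2", "c3", "c4", "c5", "c6", "c7",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8",
    "l1", "l2", "l3", "l4", "l5", "l6",
    "K1", "K2", "K3", "K4", "K5", "K6",
    "K", "M",
)


@dataclass(frozen=True)
class ParameterSet:
    """Immutable, hashable container for the 37 model constants.

    Two instances with equal values compare (and hash) equal, so a
    ``ParameterSet`` can key caches of expensive derived quantities such as
    the control steady state.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    a8: float
    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    c7: float
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float
    d7: float
    d8: float
    l1: float
    l2: float
    l3: float
    l4: float
    l5: float
    l6: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    K: float
    M: float

    def __post_init__(self) -> None:
        bad = [
            name
            for name in PARAM_NAMES
            if not (
                isinstance(getattr(self, name), (int, float))
                and math.isfinite(getattr(self, name))
                and getattr(self, name) > 0
            )
        ]
        if bad:
            raise ValueError(
                "all parameters must be strictly positive finite numbers; "
                f"offending: {', '.join(bad)}"
            )
        for name in PARAM_NAMES:
            object.__setattr__(self, name, float(getattr(self, name)))

    # -- array / mapping round trips -------------------------------------
    def as_array(self) -> np.ndarray:
        """Values in the canonical ``PARAM_NAMES`` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ParameterSet":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} values, got {len(values)}"
            )
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(mapping) - set(PARAM_NAMES))
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        missing = sorted(set(PARAM_NAMES) - set(mapping))
        if missing:
            raise ValueError(f"missing parameter keys: {', '.join(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    # -- file round trips -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        """Load from a flat YAML (or JSON) mapping of name -> value."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of parameters")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **changes: float) -> "ParameterSet":
        unknown = sorted(set(changes) - set(PARAM_NAMES))
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        return dataclasses.replace(self, **changes)
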
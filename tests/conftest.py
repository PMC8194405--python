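"""Shared fixtures: parameter sets and independent integration oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gutmuscle.model import N_SPECIES, _make_rhs
from gutmuscle.params import ParameterSet

#: effectively-zero coupling for the decoupled linear configuration
#: (ParameterSet requires strictly positive values; 1e-12 leaves the
#: closed-form error far below every tolerance used in the tests)
EPS_COUPLING = 1e-12


def make_linear_params(
    a=(0.5, 0.3, 0.2, 0.4, 0.25, 0.35, 0.45, 0.15),
    d=(0.5, 0.8, 0.3, 0.6, 0.4, 0.7, 0.55, 0.45),
) -> ParameterSet:
    """Decoupled configuration: every interaction rate effectively zero, so
    each species follows u_i(t) = (a_i/d_i)(1 - exp(-d_i t))."""
    vals = {f"a{i+1}": a[i] for i in range(8)}
    vals.update({f"d{i+1}": d[i] for i in range(8)})
    vals.update({f"c{i+1}": EPS_COUPLING for i in range(7)})
    vals.update({f"l{i+1}": EPS_COUPLING for i in range(6)})
    vals.update({f"K{i+1}": 1.0 for i in range(6)})
    vals.update({"K": 1.0, "M": 1.0})
    return ParameterSet.from_dict(vals)


#: hand-checked interacting configuration with bounded, positive dynamics
STABLE_VALUES = dict(
    a1=0.3, a2=0.3, a3=0.01, a4=0.3, a5=0.1, a6=0.3, a7=0.3, a8=0.3,
    c1=10.0, c2=0.6, c3=0.5, c4=0.12, c5=0.05, c6=0.05, c7=0.05,
    d1=1.0, d2=0.8, d3=0.3, d4=0.5, d5=0.12, d6=0.5, d7=0.5, d8=0.5,
    l1=0.05, l2=0.05, l3=0.1, l4=0.05, l5=0.1, l6=0.05,
    K1=1.0, K2=1.0, K3=1.0, K4=1.0, K5=1.0, K6=1.0, K=1.0, M=1.0,
)


@pytest.fixture(scope="session")
def linear_params() -> ParameterSet:
    return make_linear_params()


@pytest.fixture(scope="session")
def stable_params() -> ParameterSet:
    return ParameterSet.from_dict(STABLE_VALUES)


@pytest.fixture(scope="session")
def reference_params() -> ParameterSet:
    from gutmuscle.calibration import reference_parameters

    return reference_parameters()


def jittered_params(rng: np.random.Generator, scale: float = 0.1) -> ParameterSet:
    """Random positive parameter set: lognormal jitter around the stable
    template (keeps the dynamics bounded while exercising every term)."""
    base = ParameterSet.from_dict(STABLE_VALUES).as_array()
    return ParameterSet.from_array(
        base * np.exp(scale * rng.standard_normal(base.size)))


def linear_closed_form(params: ParameterSet, times: np.ndarray) -> np.ndarray:
    """u_i(t) = (a_i/d_i)(1 - e^{-d_i t}) for the decoupled configuration."""
    a = np.array([getattr(params, f"a{i+1}") for i in range(8)])
    d = np.array([getattr(params, f"d{i+1}") for i in range(8)])
    return (a / d)[None, :] * (1.0 - np.exp(-np.outer(times, d)))


def rk4_integrate(
    params: ParameterSet, s: float, horizon: float, h: float = 1e-3
) -> np.ndarray:
    """Fixed-step classical 4th-order Runge-Kutta oracle; returns the final
    state.  Independent of the adaptive solver path under test."""
    rhs = _make_rhs(params, s, "repressive")
    n = int(round(horizon / h))
    y = np.zeros(N_SPECIES)
    t = 0.0
    f = lambda ti, yi: np.asarray(rhs(ti, yi))
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y
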
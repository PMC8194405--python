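"""Core dynamics: the 8-species ODE system of the gut-muscle axis.

The state tracks dimensionless expression levels of short-chain fatty acids
(SCFAs), AKT, mTOR, atrogins, skeletal muscle mass, FoxO, TNF-alpha and
myostatin.  Every equation follows the same balance::

    du/dt = basal production + activation - deactivation - degradation

Positive feedbacks are mass-action (bilinear) terms; negative feedbacks are
Hill repression factors ``K/(u + K)`` multiplying the repressed flux.
Exercise enters through two channels only: a saturating production stimulus
``a(s) = c1*s/(s+K)`` on SCFAs, and an intensity-proportional acceleration
``d2*(1 + s/M)`` of AKT degradation, where ``M`` is the delay coefficient.

Simulations start from the all-zero state (the convention here is that
modeling begins at the removal of the exercise stimulus) and are integrated
with an adaptive Bogacki-Shampine 2(3) Runge-Kutta pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ParameterSet

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "ModelError",
    "SolverError",
    "ConvergenceError",
    "stimulus_activation",
    "degradation_multiplier",
    "hill_factor",
    "derivatives",
    "integrate",
    "find_steady_state",
    "Trajectory",
    "GutMuscleModel",
]

logger = logging.getLogger(__name__)

#: Canonical species ordering, used for every state vector in the package.
SPECIES: tuple[str, ...] = (
    "SCFAs", "AKT", "mTOR", "atr", "muscle", "FoxO", "TNFa", "myo",
)
N_SPECIES = len(SPECIES)

DEFAULT_GRID_STEP = 0.01  # hours
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


class ModelError(Exception):
    """Base class for model-layer failures."""


class SolverError(ModelError):
    """Integration failed (step-size collapse or non-finite state)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ConvergenceError(ModelError):
    """Steady-state search hit its horizon cap without converging."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def stimulus_activation(s: float, c1: float, K: float) -> float:
    """Exercise stimulus on SCFA production, ``a(s) = c1*s/(s+K)``.

    Saturating in intensity ``s``: zero at rest, approaching the gain ``c1``
    as ``s`` grows far beyond the half-saturation ``K``.
    """
    if s < 0:
        raise ValueError(f"intensity must be nonnegative, got {s}")
    if c1 <= 0 or K <= 0:
        raise ValueError("c1 and K must be strictly positive")
    return c1 * s / (s + K)


def degradation_multiplier(s: float, M: float) -> float:
    """Intensity factor on AKT degradation, ``1 + s/M``.

    ``M`` is the delay coefficient: the larger it is, the weaker the
    intensity-driven dephosphorylation of AKT, delaying its decay.
    """
    if s < 0:
        raise ValueError(f"intensity must be nonnegative, got {s}")
    if M <= 0:
        raise ValueError(f"delay coefficient must be positive, got {M}")
    return 1.0 + s / M


def hill_factor(u: float, K_half: float) -> float:
    """Hill repression factor ``K_half/(u + K_half)``, in (0, 1]."""
    if K_half <= 0:
        raise ValueError(f"half-saturation must be positive, got {K_half}")
    if np.any(np.asarray(u) < 0):
        raise ValueError("expression level must be nonnegative")
    return K_half / (u + K_half)


def _make_rhs(
    p: ParameterSet, s: float, hill_orientation: str
) -> Callable[[float, Sequence[float]], list[float]]:
    """Build a fast closure for the ODE right-hand side."""
    if hill_orientation not in ("repressive", "saturating"):
        raise ValueError(
            "hill_orientation must be 'repressive' or 'saturating', "
            f"got {hill_orientation!r}"
        )
    repressive = hill_orientation == "repressive"
    a1, a2, a3, a4, a5, a6, a7, a8 = (
        p.a1, p.a2, p.a3, p.a4, p.a5, p.a6, p.a7, p.a8)
    c2, c3, c4, c5, c6, c7 = p.c2, p.c3, p.c4, p.c5, p.c6, p.c7
    d1, d2, d3, d4, d5, d6, d7, d8 = (
        p.d1, p.d2, p.d3, p.d4, p.d5, p.d6, p.d7, p.d8)
    l1, l2, l3, l4, l5, l6 = p.l1, p.l2, p.l3, p.l4, p.l5, p.l6
    K1, K2, K3, K4, K5, K6 = p.K1, p.K2, p.K3, p.K4, p.K5, p.K6
    stim = stimulus_activation(s, p.c1, p.K) if s > 0 else 0.0
    d2s = d2 * degradation_multiplier(s, p.M)

    def rhs(t: float, y: Sequence[float]) -> list[float]:
        S, A, T, G, Mu, F, N, Y = y
        if repressive:
            h1 = K1 / (G + K1)
            h2 = K2 / (A + K2)
            h3 = K3 / (S + K3)
            h4 = K4 / (N + K4)
            h5 = K5 / (S + K5)
            h6 = K6 / (Y + K6)
        else:
            h1 = G / (G + K1)
            h2 = A / (A + K2)
            h3 = S / (S + K3)
            h4 = N / (N + K4)
            h5 = S / (S + K5)
            h6 = Y / (Y + K6)
        return [
            a1 + stim - c2 * S * A - l3 * h3 * N - l5 * h5 * Y - d1 * S,
            a2 + c2 * S * A - c3 * A * T - l2 * h2 * F
            + l4 * h4 * A + l6 * h6 * A - d2s * A,
            a3 + c3 * A - c4 * A * Mu - d3 * T,
            a4 + c5 * F * G + c6 * N * G - l1 * h1 * Mu - d4 * G,
            a5 + c4 * A * Mu - l1 * h1 * Mu - d5 * Mu,
            a6 + l2 * h2 * F + c7 * Y * F - c5 * G * F - d6 * F,
            a7 + l3 * h3 * N - l4 * h4 * A - c6 * N * G - d7 * N,
            a8 + l5 * h5 * Y - l6 * h6 * A - c7 * Y * F - d8 * Y,
        ]

    return rhs


_BLOWUP_LIMIT = 1e6


def _make_guard_events(p: ParameterSet):
    """Terminal events converting pathological dynamics into clean failures.

    The Hill factors ``K/(u+K)`` are singular at ``u = -K``; once a species
    crosses far enough below zero the repressed fluxes diverge and the state
    collapses to the pole in finite time, which an adaptive solver can only
    grind against.  The guard fires when a Hill-denominator species falls
    below half-way to its pole (or any species below -1), and a second guard
    catches blow-up beyond ``1e6``.
    """
    # floor per species: half-way to the nearest Hill pole where applicable
    floors = np.array([
        0.5 * min(p.K3, p.K5),  # SCFAs in H3, H5
        0.5 * p.K2,             # AKT in H2
        1.0,                    # mTOR (no pole)
        0.5 * p.K1,             # atrogins in H1
        1.0,                    # muscle (no pole)
        1.0,                    # FoxO (no pole)
        0.5 * p.K4,             # TNFa in H4
        0.5 * p.K6,             # myostatin in H6
    ])
    floors = np.minimum(floors, 1.0)

    def negative_guard(t, y):
        return float(np.min(np.asarray(y) + floors))

    def blowup_guard(t, y):
        return float(_BLOWUP_LIMIT - np.max(np.abs(y)))

    negative_guard.terminal = True
    blowup_guard.terminal = True
    return [negative_guard, blowup_guard]


def derivatives(
    state: Sequence[float],
    params: ParameterSet,
    s: float = 0.0,
    hill_orientation: str = "repressive",
) -> np.ndarray:
    """Time derivatives of the 8 species at a given state and intensity."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have length {N_SPECIES}, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ModelError("state contains non-finite entries")
    if s < 0:
        raise ValueError(f"intensity must be nonnegative, got {s}")
    rhs = _make_rhs(params, s, hill_orientation)
    return np.asarray(rhs(0.0, y), dtype=float)


@dataclass
class Trajectory:
    """Dense solution of one integration under one condition.

    ``states`` has one row per time point, columns ordered as ``SPECIES``.
    ``flagged`` records that a species dipped below zero during integration
    (the model does not guarantee positivity; the excursion is reported, not
    masked).
    """

    times: np.ndarray
    states: np.ndarray
    intensity: float
    params: ParameterSet
    flagged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (
            self.times.size, N_SPECIES,
        ):
            raise ValueError("inconsistent trajectory shapes")
        if self.times[0] != 0.0:
            raise ValueError("trajectory must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def at(self, t: float | Sequence[float]) -> np.ndarray:
        """Linear interpolation of the state on the reporting grid."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if t_arr.min() < self.times[0] or t_arr.max() > self.times[-1]:
            raise ValueError(
                f"requested time outside [{self.times[0]}, {self.times[-1]}]"
            )
        out = np.column_stack(
            [np.interp(t_arr, self.times, self.states[:, j])
             for j in range(N_SPECIES)]
        )
        return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def to_frame(self, param_set_id: str = "default") -> pd.DataFrame:
        """Tidy long-format table: time, species, value, intensity, id."""
        n = self.times.size
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, N_SPECIES),
                "species": np.tile(np.asarray(SPECIES, dtype=object), n),
                "value": self.states.ravel(),
                "intensity": self.intensity,
                "param_set_id": param_set_id,
            }
        )

    def to_csv(self, path: str | Path, param_set_id: str = "default") -> None:
        from .outputs import float_repr

        # repr round trip: every value exactly recoverable from the file
        self.to_frame(param_set_id).to_csv(
            path, index=False, float_format=float_repr)


def integrate(
    params: ParameterSet,
    s: float = 0.0,
    initial: Sequence[float] | None = None,
    horizon: float = 24.0,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    hill_orientation: str = "repressive",
    dense: bool = True,
    method: str = "RK23",
) -> Trajectory:
    """Integrate the system over ``[0, horizon]`` hours.

    Uses an adaptive explicit Runge-Kutta 2(3) pair (Bogacki-Shampine) with
    the configured error tolerances and reports the solution on a uniform
    grid of ``grid_step`` hours.  Deterministic for fixed inputs.
    ``method`` accepts any solve_ivp solver name (e.g. "LSODA" when probing
    stiff corners of parameter space); the default matches the 2(3) pair.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    y0 = np.zeros(N_SPECIES) if initial is None else np.asarray(
        initial, dtype=float)
    if y0.shape != (N_SPECIES,):
        raise ValueError(f"initial state must have length {N_SPECIES}")
    if dense:
        n = max(1, int(round(horizon / grid_step)))
        t_eval = np.linspace(0.0, horizon, n + 1)
    else:
        t_eval = np.array([0.0, horizon])
    rhs = _make_rhs(params, s, hill_orientation)
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, events=_make_guard_events(params),
    )
    if sol.status == 1:  # a terminal guard fired
        t_fail = float(
            min(te[0] for te in sol.t_events if te.size))
        raise SolverError(
            f"state left the admissible region at t={t_fail:.4g} h "
            "(deep negative excursion or blow-up)", time=t_fail,
        )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(
            f"integration failed at t={t_fail:.4g} h: {sol.message}",
            time=t_fail,
        )
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))
        t_fail = float(sol.t[bad[0, 0]])
        raise SolverError(
            f"non-finite state at t={t_fail:.4g} h", time=t_fail)
    flagged = bool(states.min() < -atol)
    if flagged:
        j = int(np.unravel_index(np.argmin(states), states.shape)[1])
        logger.warning(
            "species %s dropped to %.3g (below zero) during integration "
            "at s=%.4g; trajectory flagged",
            SPECIES[j], float(states.min()), s,
        )
    return Trajectory(sol.t, states, s, params, flagged=flagged)


def _newton_polish(rhs, state: np.ndarray) -> np.ndarray | None:
    """Refine an almost-steady state by solving rhs(y) = 0 from it."""
    from scipy.optimize import root

    sol = root(lambda y: np.asarray(rhs(0.0, y)), state, method="hybr")
    return sol.x if sol.success else None


def find_steady_state(
    params: ParameterSet,
    s: float = 0.0,
    tol: float = 1e-8,
    *,
    horizon_cap: float = 10_000.0,
    hill_orientation: str = "repressive",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Relax from the zero state until the derivative max-norm falls below ``tol``.

    Integrates in geometrically growing chunks up to ``horizon_cap`` hours
    with a stiffness-switching solver (LSODA; only the endpoint matters
    here, so the trajectory solver's method does not apply), then polishes
    with a Newton root solve once close.  Raises :class:`ConvergenceError`
    (carrying the final residual) if the cap is reached first.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rhs = _make_rhs(params, s, hill_orientation)
    state = np.zeros(N_SPECIES)
    elapsed, chunk = 0.0, 100.0
    residual = float(np.max(np.abs(rhs(0.0, state))))
    while elapsed < horizon_cap:
        chunk = min(chunk, horizon_cap - elapsed)
        sol = solve_ivp(
            rhs, (0.0, chunk), state, method="LSODA", rtol=rtol, atol=atol,
            events=_make_guard_events(params),
        )
        if sol.status == 1:
            t_fail = elapsed + float(
                min(te[0] for te in sol.t_events if te.size))
            raise SolverError(
                f"state left the admissible region at t={t_fail:.4g} h "
                "during steady-state relaxation", time=t_fail,
            )
        if not sol.success:
            raise SolverError(
                f"steady-state relaxation failed: {sol.message}",
                time=elapsed + float(sol.t[-1]),
            )
        state = sol.y[:, -1]
        elapsed += chunk
        chunk *= 2.0
        residual = float(np.max(np.abs(rhs(0.0, state))))
        if residual < tol:
            return state
        if residual < 1e-3:
            # near the attractor the relaxation residual is limited by the
            # integrator's error floor; polish with a root solve instead
            polished = _newton_polish(rhs, state)
            if polished is not None:
                p_resid = float(np.max(np.abs(rhs(0.0, polished))))
                if p_resid < tol and np.max(
                    np.abs(polished - state)
                ) < 1e-2 * (1.0 + np.max(np.abs(state))):
                    return polished
    raise ConvergenceError(
        f"no steady state within {horizon_cap} h "
        f"(final residual {residual:.3g} > tol {tol:.3g})",
        residual=residual,
    )


class GutMuscleModel:
    """Object-oriented entry point bundling a parameter set with its dynamics.

    Thin facade over the module-level functions; useful when running several
    conditions against one parameter set, since the control steady state is
    cached on the instance.
    """

    def __init__(
        self,
        params: ParameterSet,
        hill_orientation: str = "repressive",
    ) -> None:
        if hill_orientation not in ("repressive", "saturating"):
            raise ValueError(f"bad hill_orientation {hill_orientation!r}")
        self.params = params
        self.hill_orientation = hill_orientation
        self._baseline: np.ndarray | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **kw) -> "GutMuscleModel":
        return cls(ParameterSet.from_yaml(path), **kw)

    def derivatives(self, state: Sequence[float], s: float = 0.0) -> np.ndarray:
        return derivatives(state, self.params, s, self.hill_orientation)

    def simulate(self, s: float = 0.0, horizon: float = 24.0, **opts) -> Trajectory:
        return integrate(
            self.params, s, horizon=horizon,
            hill_orientation=self.hill_orientation, **opts,
        )

    def steady_state(self, s: float = 0.0, tol: float = 1e-8, **opts) -> np.ndarray:
        return find_steady_state(
            self.params, s, tol,
            hill_orientation=self.hill_orientation, **opts,
        )

    def baseline(self, tol: float = 1e-8) -> np.ndarray:
        """Control steady state (no exercise), cached."""
        if self._baseline is None:
            self._baseline = self.steady_state(0.0, tol)
        return self._baseline
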
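"""Simulation protocols: baselines, conditions, sweeps, grids and ensembles.

The protocols mirror how an exercise-physiology study would exercise the
model:

* a control baseline (no stimulus) providing the fold-change denominator;
* single conditions at a given intensity with discrete sampling at
  0/3/6/24 h next to the continuous dynamics;
* a graded-intensity sweep spanning a 4-fold range in 10 steps;
* replicated noise ensembles, perturbing every parameter with Gaussian
  noise of small amplitude, across a factorial delay-coefficient x
  intensity grid.

All randomness flows from explicit integer seeds through counter-based
(positional) streams, so grid cells are independent of evaluation order and
full runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import summaries
from .model import (
    SPECIES,
    ModelError,
    Trajectory,
    find_steady_state,
    integrate,
)
from .params import PARAM_NAMES, ParameterSet

__all__ = [
    "ConditionSpec",
    "EnsembleSpec",
    "LOW_MODERATE_HIGH",
    "control_baseline",
    "ConditionResult",
    "run_condition",
    "sample_timepoints",
    "default_intensity_grid",
    "SweepResult",
    "intensity_sweep",
    "perturb_parameters",
    "EnsembleResult",
    "noise_ensemble",
    "GridResult",
    "delay_intensity_grid",
    "preset_720",
]

logger = logging.getLogger(__name__)

#: Representative low/moderate/high intensity triplet. The span is 1.5-fold
#: (high = 1.5 x low), the ratio between the 45% and ~70% one-repetition
#: maximum loads the triplet stands for; mapping to %1RM is display-only.
LOW_MODERATE_HIGH: tuple[float, float, float] = (1.0, 1.25, 1.5)

DEFAULT_SAMPLING_TIMES = (0.0, 3.0, 6.0, 24.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One simulation condition: intensity, optional delay override, horizon."""

    s: float
    M_override: float | None = None
    horizon: float = 24.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"intensity must be nonnegative, got {self.s}")
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")
        if self.M_override is not None and self.M_override <= 0:
            raise ValueError("M_override must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """Replication scheme for noise-perturbation ensembles."""

    n_reps: int = 20
    noise_amplitude: float = 0.001
    seed: int = 0
    noise_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be nonnegative")
        if self.noise_mode not in ("additive", "relative"):
            raise ValueError(
                f"noise_mode must be 'additive' or 'relative', "
                f"got {self.noise_mode!r}"
            )


def effective_params(params: ParameterSet, cond: ConditionSpec) -> ParameterSet:
    if cond.M_override is None:
        return params
    return params.replace(M=cond.M_override)


_BASELINE_CACHE: dict[tuple, np.ndarray] = {}


def control_baseline(
    params: ParameterSet,
    *,
    tol: float = 1e-8,
    hill_orientation: str = "repressive",
    cache: bool = True,
) -> np.ndarray:
    """No-exercise steady state, the fold-change denominator.

    Cached per parameter set: repeated calls return the identical vector.
    (The delay coefficient M does not enter at s=0, so the baseline is
    shared across delay-grid cells.)
    """
    key = (params, hill_orientation, tol)
    if cache and key in _BASELINE_CACHE:
        return _BASELINE_CACHE[key].copy()
    state = find_steady_state(
        params, 0.0, tol, hill_orientation=hill_orientation)
    if cache:
        _BASELINE_CACHE[key] = state.copy()
    return state


@dataclass
class ConditionResult:
    """Raw and fold-change trajectories for one condition."""

    condition: ConditionSpec
    trajectory: Trajectory
    fold: Trajectory
    baseline: np.ndarray


def run_condition(
    params: ParameterSet,
    cond: ConditionSpec,
    *,
    baseline: np.ndarray | None = None,
    hill_orientation: str = "repressive",
    **solver_opts,
) -> ConditionResult:
    """Integrate one condition from the zero state and normalize by control."""
    p_eff = effective_params(params, cond)
    if baseline is None:
        baseline = control_baseline(
            params, hill_orientation=hill_orientation)
    try:
        traj = integrate(
            p_eff, cond.s, horizon=cond.horizon,
            hill_orientation=hill_orientation, **solver_opts,
        )
    except ModelError as err:
        err.args = (f"condition {cond.label or f's={cond.s}'}: {err}",)
        raise
    fold = summaries.fold_change_series(traj, baseline)
    return ConditionResult(cond, traj, fold, baseline)


def sample_timepoints(
    traj: Trajectory, times: Sequence[float] = DEFAULT_SAMPLING_TIMES
) -> pd.DataFrame:
    """Discrete sampling of a trajectory at the given hours.

    Mimics the wet-lab protocol of assaying at baseline, 3, 6 and 24 h.
    Values are linearly interpolated on the dense reporting grid; times
    outside the horizon raise.
    """
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < traj.times[0] or t.max() > traj.times[-1]):
        raise ValueError(
            f"sampling times must lie within "
            f"[{traj.times[0]}, {traj.times[-1]}] h"
        )
    sampled = traj.at(t)
    return pd.DataFrame(
        {
            "time": np.repeat(t, len(SPECIES)),
            "species": np.tile(np.asarray(SPECIES, dtype=object), t.size),
            "value": sampled.ravel(),
            "intensity": traj.intensity,
        }
    )


def default_intensity_grid(
    s_low: float = 1.0, n: int = 10, span: float = 4.0
) -> np.ndarray:
    """Graded intensities: ``n`` equally spaced values over [s_low, span*s_low]."""
    if s_low <= 0 or span <= 1 or n < 2:
        raise ValueError("need s_low > 0, span > 1 and n >= 2")
    return np.linspace(s_low, span * s_low, n)


_MUSCLE = SPECIES.index("muscle")


@dataclass
class SweepResult:
    """Maximized muscle mass across a graded-intensity sweep.

    One record per intensity (the s=0 entry is the control). ``max_fold`` is
    the maximum over the horizon of the muscle fold change relative to the
    control steady state.
    """

    intensities: np.ndarray
    max_fold: np.ndarray
    peak_time: np.ndarray
    baseline_muscle: float
    flagged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intensity": self.intensities,
                "max_muscle_fold": self.max_fold,
                "peak_time": self.peak_time,
                "flagged": self.flagged,
            }
        )

    def exercised(self) -> "SweepResult":
        """Drop the s=0 control entry."""
        mask = self.intensities > 0
        return SweepResult(
            self.intensities[mask], self.max_fold[mask],
            self.peak_time[mask], self.baseline_muscle, self.flagged[mask],
        )


def intensity_sweep(
    params: ParameterSet,
    intensities: Sequence[float] | None = None,
    *,
    horizon: float = 24.0,
    include_control: bool = True,
    hill_orientation: str = "repressive",
    **solver_opts,
) -> SweepResult:
    """Maximized muscle fold change across graded intensities.

    A failing intensity is recorded as NaN and flagged instead of aborting
    the sweep.
    """
    if intensities is None:
        intensities = default_intensity_grid()
    grid = np.asarray(intensities, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("intensities must be nonnegative and nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("intensities must be sorted ascending")
    if include_control and (grid.size == 0 or grid[0] != 0.0):
        grid = np.concatenate([[0.0], grid])
    baseline = control_baseline(params, hill_orientation=hill_orientation)
    max_fold = np.full(grid.size, np.nan)
    peak_time = np.full(grid.size, np.nan)
    flagged = np.zeros(grid.size, dtype=bool)
    for i, s in enumerate(grid):
        try:
            res = run_condition(
                params, ConditionSpec(s=float(s), horizon=horizon),
                baseline=baseline, hill_orientation=hill_orientation,
                **solver_opts,
            )
        except ModelError as err:
            logger.warning("sweep intensity %.4g failed: %s", s, err)
            flagged[i] = True
            continue
        max_fold[i], peak_time[i] = summaries.peak(
            res.fold.times, res.fold.states[:, _MUSCLE])
        flagged[i] = res.trajectory.flagged
    return SweepResult(
        grid, max_fold, peak_time, float(baseline[_MUSCLE]), flagged)


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # counter-based: the stream depends only on (seed, replicate), not on
    # how many replicates were drawn before.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(replicate_index)]))


def replicate_seed(seed: int, replicate_index: int) -> int:
    """Stable integer identifying one replicate's stream (for manifests)."""
    state = np.random.SeedSequence(
        [int(seed), int(replicate_index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def perturb_parameters(
    params: ParameterSet, spec: EnsembleSpec, replicate_index: int
) -> ParameterSet:
    """Gaussian perturbation of all 37 parameters for one replicate.

    Additive mode replaces each parameter ``p`` by ``p + amplitude*z`` with
    ``z ~ N(0,1)`` i.i.d.; relative mode uses ``p*(1 + amplitude*z)``.  A
    perturbed value that lands at or below zero is redrawn (and the event
    logged) so the parameter set stays admissible.
    """
    if not 0 <= replicate_index < spec.n_reps:
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {spec.n_reps})")
    if spec.noise_amplitude == 0:
        return params
    rng = _replicate_rng(spec.seed, replicate_index)
    arr = params.as_array()
    z = rng.standard_normal(arr.size)
    if spec.noise_mode == "additive":
        new = arr + spec.noise_amplitude * z
    else:
        new = arr * (1.0 + spec.noise_amplitude * z)
    for i in np.nonzero(new <= 0)[0]:
        while new[i] <= 0:
            logger.info(
                "redrawing nonpositive perturbed parameter %s "
                "(replicate %d)", PARAM_NAMES[i], replicate_index,
            )
            if spec.noise_mode == "additive":
                new[i] = arr[i] + spec.noise_amplitude * rng.standard_normal()
            else:
                new[i] = arr[i] * (
                    1.0 + spec.noise_amplitude * rng.standard_normal())
    return ParameterSet.from_array(new)


@dataclass
class EnsembleResult:
    """Replicate values of maximized muscle fold for one (intensity, M) cell."""

    condition: ConditionSpec
    spec: EnsembleSpec
    values: np.ndarray
    seeds: tuple[int, ...]
    flagged: np.ndarray

    @property
    def M(self) -> float:
        return self.condition.M_override if self.condition.M_override else np.nan

    def median(self) -> float:
        ok = self.values[np.isfinite(self.values)]
        return float(np.median(ok)) if ok.size else float("nan")

    def box(self) -> summaries.BoxStats:
        return summaries.boxplot_stats(
            self.values[np.isfinite(self.values)])


def noise_ensemble(
    params: ParameterSet,
    cond: ConditionSpec,
    spec: EnsembleSpec,
    *,
    baseline: np.ndarray | None = None,
    per_replicate_baseline: bool = False,
    hill_orientation: str = "repressive",
    **solver_opts,
) -> EnsembleResult:
    """Replicated noise-perturbation experiment for one condition.

    Each replicate perturbs the parameters, re-integrates the condition and
    records the maximized muscle fold change.  The fold-change denominator
    is the UNPERTURBED control baseline (the control is a separate,
    stimulus-free experiment); set ``per_replicate_baseline=True`` to
    recompute the baseline under each replicate's perturbed parameters.
    A failing replicate is flagged and recorded as NaN, not fatal.
    """
    p_eff = effective_params(params, cond)
    if baseline is None:
        baseline = control_baseline(
            params, hill_orientation=hill_orientation)
    values = np.full(spec.n_reps, np.nan)
    flagged = np.zeros(spec.n_reps, dtype=bool)
    seeds = tuple(replicate_seed(spec.seed, i) for i in range(spec.n_reps))
    for i in range(spec.n_reps):
        p_i = perturb_parameters(p_eff, spec, i)
        try:
            traj = integrate(
                p_i, cond.s, horizon=cond.horizon,
                hill_orientation=hill_orientation, dense=True, **solver_opts,
            )
            denom = (
                control_baseline(
                    p_i.replace(M=params.M),
                    hill_orientation=hill_orientation, cache=False)
                if per_replicate_baseline else baseline
            )
            fold = summaries.fold_change_series(traj, denom)
            values[i], _ = summaries.peak(
                fold.times, fold.states[:, _MUSCLE])
            flagged[i] = traj.flagged
        except ModelError as err:
            logger.warning(
                "replicate %d at s=%.4g failed: %s", i, cond.s, err)
            flagged[i] = True
    return EnsembleResult(cond, spec, values, seeds, flagged)


def cell_seed(master_seed: int, m_index: int, s_index: int) -> int:
    """Positional per-cell seed: independent of cell evaluation order."""
    state = np.random.SeedSequence(
        [int(master_seed), int(m_index), int(s_index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


@dataclass
class GridResult:
    """Full factorial delay-coefficient x intensity grid of ensembles."""

    M_values: np.ndarray
    intensities: np.ndarray
    spec: EnsembleSpec
    cells: list[list[EnsembleResult]]  # [m_index][s_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, M in enumerate(self.M_values):
            for si, s in enumerate(self.intensities):
                cell = self.cells[mi][si]
                for r in range(cell.spec.n_reps):
                    rows.append(
                        {
                            "M": float(M),
                            "intensity": float(s),
                            "replicate": r,
                            "seed": cell.seeds[r],
                            "max_muscle_fold": cell.values[r],
                            "flagged": bool(cell.flagged[r]),
                        }
                    )
        return pd.DataFrame(rows)

    def median_table(self) -> pd.DataFrame:
        """Replicate-median maximized muscle fold per (M, intensity) cell."""
        rows = [
            {
                "M": float(M),
                "intensity": float(s),
                "median_max_fold": self.cells[mi][si].median(),
            }
            for mi, M in enumerate(self.M_values)
            for si, s in enumerate(self.intensities)
        ]
        return pd.DataFrame(rows)

    def boxstats_table(self) -> pd.DataFrame:
        rows = []
        for mi, M in enumerate(self.M_values):
            for si, s in enumerate(self.intensities):
                b = self.cells[mi][si].box()
                rows.append(
                    {
                        "M": float(M),
                        "intensity": float(s),
                        "median": b.median,
                        "q1": b.q1,
                        "q3": b.q3,
                        "whisker_low": b.whisker_low,
                        "whisker_high": b.whisker_high,
                        "n_outliers": len(b.outliers),
                    }
                )
        return pd.DataFrame(rows)


def delay_intensity_grid(
    params: ParameterSet,
    M_values: Sequence[float] | None = None,
    intensities: Sequence[float] | None = None,
    spec: EnsembleSpec = EnsembleSpec(),
    *,
    hill_orientation: str = "repressive",
    **solver_opts,
) -> GridResult:
    """Factorial grid of noise ensembles over delay coefficients and intensities.

    Default delay grid is ``M x {1, 2, 3, 4}`` (a linear 4-fold span of the
    parameter set's own M); default intensities are the 10-point graded
    sweep.  Each cell draws replicates from a positional stream derived from
    the master seed and the (M, intensity) indices, so cells are independent
    of evaluation order.
    """
    if M_values is None:
        M_values = params.M * np.array([1.0, 2.0, 3.0, 4.0])
    if intensities is None:
        intensities = default_intensity_grid()
    M_arr = np.asarray(M_values, dtype=float)
    s_arr = np.asarray(intensities, dtype=float)
    baseline = control_baseline(params, hill_orientation=hill_orientation)
    cells: list[list[EnsembleResult]] = []
    for mi, M in enumerate(M_arr):
        row = []
        for si, s in enumerate(s_arr):
            cspec = dataclasses.replace(
                spec, seed=cell_seed(spec.seed, mi, si))
            row.append(
                noise_ensemble(
                    params,
                    ConditionSpec(s=float(s), M_override=float(M)),
                    cspec,
                    baseline=baseline,
                    hill_orientation=hill_orientation,
                    **solver_opts,
                )
            )
        cells.append(row)
    return GridResult(M_arr, s_arr, spec, cells)


def preset_720(
    params: ParameterSet, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, EnsembleSpec]:
    """720-sample factorial preset: 10 intensities x 18 replicates x 4 delay
    coefficients.  One consistent factorization of a 720-run budget over the
    default grids; pass the pieces to :func:`delay_intensity_grid`."""
    return (
        params.M * np.array([1.0, 2.0, 3.0, 4.0]),
        default_intensity_grid(),
        EnsembleSpec(n_reps=18, seed=seed),
    )
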
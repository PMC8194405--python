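"""Recover a reference parameter set from printed quantitative anchors.

The model's parameter table is dimensionless and, for the most part, not
measurable directly; what is available are a handful of headline observables
(peak fold changes, peak times, the span of the intensity sweep, ensemble
medians at two delay coefficients).  This module turns those observables
into a weighted relative-error loss and searches the admissible box for a
parameter set that reproduces them.

Identifiability is not claimed and not needed: with 37 parameters and at
most 8 anchors the problem is underdetermined, so acceptance is anchor
reproduction, not parameter recovery.  The search is a deterministic
Latin-hypercube scan in log space followed by Nelder-Mead refinement from
the best point, with the best-ever evaluation tracked so that a larger
budget can never end worse.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.stats import qmc

from . import experiments, summaries
from .experiments import ConditionSpec, EnsembleSpec
from .model import SPECIES, ModelError, find_steady_state, integrate
from .params import PARAM_NAMES, ParameterSet

__all__ = [
    "Anchor",
    "AnchorSet",
    "default_anchors",
    "AnchorEvaluator",
    "anchor_predictions",
    "anchor_loss",
    "CalibrationResult",
    "calibrate",
    "default_bounds",
    "reference_parameters",
]

FAILURE_LOSS = 1e6  # sentinel when no anchor can be evaluated at all
ANCHOR_PENALTY = 100.0  # per-anchor penalty when its observable fails

_MUSCLE = SPECIES.index("muscle")
_AKT = SPECIES.index("AKT")
_MTOR = SPECIES.index("mTOR")
_SCFA = SPECIES.index("SCFAs")
_MYO = SPECIES.index("myo")


@dataclass(frozen=True)
class Anchor:
    """One target observable with its weight in the loss."""

    observable: str
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("anchor targets must be positive")
        if self.weight <= 0:
            raise ValueError("anchor weights must be positive")


@dataclass(frozen=True)
class AnchorSet:
    """Immutable collection of anchors, serializable to a flat YAML list."""

    anchors: tuple[Anchor, ...]

    def __iter__(self):
        return iter(self.anchors)

    def __len__(self) -> int:
        return len(self.anchors)

    def names(self) -> tuple[str, ...]:
        return tuple(a.observable for a in self.anchors)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnchorSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError(f"{path}: expected a list of anchors")
        return cls(
            tuple(
                Anchor(r["observable"], float(r["target"]),
                       float(r.get("weight", 1.0)))
                for r in raw
            )
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                [
                    {"observable": a.observable, "target": a.target,
                     "weight": a.weight}
                    for a in self.anchors
                ],
                fh, sort_keys=False,
            )


def default_anchors() -> AnchorSet:
    """The headline anchors the reference parameter set is calibrated to:
    peak AKT/mTOR fold changes at high intensity, the span of the
    10-intensity sweep of maximized muscle mass, SCFA and myostatin peak
    times, and the replicate-median maximized muscle fold at the base and
    4x delay coefficients."""
    return AnchorSet(
        (
            Anchor("akt_peak_fold_high", 3.9),
            Anchor("mtor_peak_fold_high", 5.5),
            Anchor("muscle_fold_min_sweep", 1.2),
            Anchor("muscle_fold_max_sweep", 1.7),
            Anchor("scfa_peak_time_h", 2.0),
            Anchor("myo_peak_time_h", 4.0),
            Anchor("median_peak_muscle_fold_baseM", 1.8),
            Anchor("median_peak_muscle_fold_4M", 4.6),
        )
    )


class AnchorEvaluator:
    """Computes anchor observables for one parameter set, sharing work.

    The control baseline, the high-intensity condition and the intensity
    sweeps are computed at most once each, whatever subset of observables is
    requested.  Noise-median observables use a fixed seed and a configurable
    replicate count (reduced inside the calibration loss for speed, full
    for final verification).
    """

    #: intensity used for the "high" condition of the low/moderate/high triplet
    S_HIGH = experiments.LOW_MODERATE_HIGH[2]

    def __init__(
        self,
        params: ParameterSet,
        *,
        n_reps: int = 5,
        noise_amplitude: float = 0.001,
        seed: int = 0,
        horizon: float = 24.0,
        grid_step: float = 0.01,
        hill_orientation: str = "repressive",
        method: str = "RK23",
        ss_tol: float = 1e-8,
        ss_horizon_cap: float = 10_000.0,
    ) -> None:
        self.params = params
        self.n_reps = int(n_reps)
        self.noise_amplitude = float(noise_amplitude)
        self.seed = int(seed)
        self.horizon = float(horizon)
        self.grid_step = float(grid_step)
        self.hill_orientation = hill_orientation
        self.method = method
        self.ss_tol = float(ss_tol)
        self.ss_horizon_cap = float(ss_horizon_cap)
        self._cache: dict[str, object] = {}

    # -- shared intermediates -------------------------------------------
    def _baseline(self) -> np.ndarray:
        if "baseline" not in self._cache:
            self._cache["baseline"] = find_steady_state(
                self.params, 0.0, self.ss_tol,
                horizon_cap=self.ss_horizon_cap,
                hill_orientation=self.hill_orientation)
        return self._cache["baseline"]

    def _high_fold(self):
        if "high_fold" not in self._cache:
            traj = integrate(
                self.params, self.S_HIGH, horizon=self.horizon,
                grid_step=self.grid_step, method=self.method,
                hill_orientation=self.hill_orientation)
            self._cache["high_fold"] = summaries.fold_change_series(
                traj, self._baseline())
        return self._cache["high_fold"]

    def _sweep_max_folds(self, m_factor: float) -> np.ndarray:
        """Per-intensity maximized muscle fold; failing intensities are NaN
        (mirrors the sweep protocol, which flags rather than aborts)."""
        key = f"sweep_{m_factor}"
        if key not in self._cache:
            p = (self.params if m_factor == 1.0
                 else self.params.replace(M=self.params.M * m_factor))
            baseline = self._baseline()
            grid = experiments.default_intensity_grid()
            folds = np.full(grid.size, np.nan)
            for i, s in enumerate(grid):
                try:
                    traj = integrate(
                        p, float(s), horizon=self.horizon,
                        grid_step=self.grid_step, method=self.method,
                        hill_orientation=self.hill_orientation)
                except ModelError:
                    continue
                fold = summaries.fold_change_series(traj, baseline)
                folds[i], _ = summaries.peak(
                    fold.times, fold.states[:, _MUSCLE])
            if not np.any(np.isfinite(folds)):
                raise ModelError("every sweep intensity failed")
            self._cache[key] = folds
        return self._cache[key]

    def _median_peak(self, m_factor: float) -> float:
        """Max over intensities of the replicate-median maximized muscle fold."""
        key = f"median_{m_factor}"
        if key not in self._cache:
            if self.n_reps == 1 or self.noise_amplitude == 0:
                self._cache[key] = float(
                    np.nanmax(self._sweep_max_folds(m_factor)))
                return self._cache[key]
            M = self.params.M * m_factor
            spec = EnsembleSpec(
                n_reps=self.n_reps, noise_amplitude=self.noise_amplitude,
                seed=self.seed)
            baseline = self._baseline()
            grid = experiments.default_intensity_grid()
            medians = np.empty(grid.size)
            for si, s in enumerate(grid):
                cspec = dataclasses.replace(
                    spec,
                    seed=experiments.cell_seed(self.seed, int(m_factor), si))
                cell = experiments.noise_ensemble(
                    self.params, ConditionSpec(s=float(s), M_override=M),
                    cspec, baseline=baseline,
                    hill_orientation=self.hill_orientation,
                    grid_step=self.grid_step)
                medians[si] = cell.median()
            if not np.any(np.isfinite(medians)):
                raise ModelError("every ensemble cell failed")
            self._cache[key] = float(np.nanmax(medians))
        return self._cache[key]

    # -- observables -----------------------------------------------------
    def akt_peak_fold_high(self) -> float:
        f = self._high_fold()
        return summaries.peak(f.times, f.states[:, _AKT])[0]

    def mtor_peak_fold_high(self) -> float:
        f = self._high_fold()
        return summaries.peak(f.times, f.states[:, _MTOR])[0]

    def scfa_peak_time_h(self) -> float:
        f = self._high_fold()
        return summaries.peak(f.times, f.states[:, _SCFA])[1]

    def myo_peak_time_h(self) -> float:
        f = self._high_fold()
        return summaries.peak(f.times, f.states[:, _MYO])[1]

    def muscle_fold_min_sweep(self) -> float:
        return float(np.nanmin(self._sweep_max_folds(1.0)))

    def muscle_fold_max_sweep(self) -> float:
        return float(np.nanmax(self._sweep_max_folds(1.0)))

    def median_peak_muscle_fold_baseM(self) -> float:
        return self._median_peak(1.0)

    def median_peak_muscle_fold_4M(self) -> float:
        return self._median_peak(4.0)

    OBSERVABLES = (
        "akt_peak_fold_high",
        "mtor_peak_fold_high",
        "scfa_peak_time_h",
        "myo_peak_time_h",
        "muscle_fold_min_sweep",
        "muscle_fold_max_sweep",
        "median_peak_muscle_fold_baseM",
        "median_peak_muscle_fold_4M",
    )

    def evaluate(self, name: str) -> float:
        if name not in self.OBSERVABLES:
            raise KeyError(
                f"unknown observable {name!r}; known: {self.OBSERVABLES}")
        return float(getattr(self, name)())


def anchor_predictions(
    params: ParameterSet,
    anchors: AnchorSet,
    **evaluator_opts,
) -> dict[str, float]:
    """Predicted value of every anchor observable, deterministically.

    An observable whose underlying simulation fails is reported as NaN.
    """
    ev = AnchorEvaluator(params, **evaluator_opts)
    preds = {}
    for a in anchors:
        try:
            preds[a.observable] = ev.evaluate(a.observable)
        except ModelError:
            preds[a.observable] = float("nan")
    return preds


def anchor_loss(
    params: ParameterSet,
    anchors: AnchorSet,
    **evaluator_opts,
) -> float:
    """Weighted sum of squared relative errors over the anchors.

    A failing observable contributes a large bounded penalty per anchor
    (rather than poisoning the whole loss), so the search still sees
    partial credit in pathological corners of the box; if nothing at all
    can be evaluated the sentinel ``FAILURE_LOSS`` is returned.
    """
    preds = anchor_predictions(params, anchors, **evaluator_opts)
    if not any(np.isfinite(v) for v in preds.values()):
        return FAILURE_LOSS
    loss = 0.0
    for a in anchors:
        pred = preds[a.observable]
        if not np.isfinite(pred):
            loss += a.weight * ANCHOR_PENALTY
        else:
            loss += a.weight * ((pred - a.target) / a.target) ** 2
    return float(loss)


def default_bounds() -> dict[str, tuple[float, float]]:
    """Admissible box: (1e-4, 10) for rates, (1e-2, 10) for half-saturations
    and the delay coefficient (dimensionless O(1) regime)."""
    bounds = {}
    for name in PARAM_NAMES:
        if name.startswith("K") or name == "M":
            bounds[name] = (1e-2, 10.0)
        else:
            bounds[name] = (1e-4, 10.0)
    return bounds


@dataclass
class CalibrationResult:
    """Best parameter set found, its loss, and per-anchor diagnostics."""

    params: ParameterSet
    loss: float
    n_evals: int
    below_tolerance: bool
    anchors: AnchorSet
    predictions: dict[str, float]
    history: pd.DataFrame  # eval_index, loss, best_loss

    def residual_table(self) -> pd.DataFrame:
        rows = []
        for a in self.anchors:
            pred = self.predictions[a.observable]
            rows.append(
                {
                    "observable": a.observable,
                    "target": a.target,
                    "predicted": pred,
                    "rel_error": (pred - a.target) / a.target,
                    "weight": a.weight,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Anchor calibration result",
            "=" * 68,
            f"evaluations: {self.n_evals}    achieved loss: {self.loss:.6g}"
            f"    below tolerance: {self.below_tolerance}",
            "-" * 68,
            f"{'observable':34s}{'target':>10s}{'predicted':>12s}"
            f"{'rel.err':>10s}",
        ]
        for _, r in self.residual_table().iterrows():
            lines.append(
                f"{r.observable:34s}{r.target:10.4g}{r.predicted:12.4g}"
                f"{r.rel_error:10.2%}"
            )
        lines.append("=" * 68)
        return "\n".join(lines)


def _project(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.clip(values, lo, hi)


def calibrate(
    anchors: AnchorSet,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    budget: int = 200,
    seed: int = 0,
    *,
    x0: ParameterSet | None = None,
    free: Sequence[str] | None = None,
    loss_tolerance: float = 1e-2,
    evaluator_opts: Mapping | None = None,
    n_lhs: int = 64,
    verbose: bool = False,
) -> CalibrationResult:
    """Bounded global-then-local anchor search.

    A fixed Latin-hypercube sample of the (log-scaled) box is scanned first
    (at most ``n_lhs`` points, fewer if the budget is smaller), then
    Nelder-Mead refines from the best point until the evaluation budget is
    spent.  ``free`` restricts the search to a subset of parameter names,
    holding the others at ``x0`` (which is then required).  The best
    evaluation ever seen is returned, so the achieved loss is non-increasing
    in the budget, and the whole procedure is deterministic for a fixed
    seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    bounds = dict(default_bounds() if bounds is None else bounds)
    unknown = sorted(set(bounds) - set(PARAM_NAMES))
    if unknown:
        raise ValueError(f"bounds for unknown parameters: {unknown}")
    free = list(PARAM_NAMES) if free is None else list(free)
    if set(free) - set(PARAM_NAMES):
        raise ValueError("free lists unknown parameter names")
    if x0 is None:
        if set(free) != set(PARAM_NAMES):
            raise ValueError("x0 is required when free is a strict subset")
        mid = {
            n: float(np.sqrt(bounds[n][0] * bounds[n][1]))
            for n in PARAM_NAMES
        }
        x0 = ParameterSet.from_dict(mid)
    ev_opts = dict(evaluator_opts or {})

    free_idx = [PARAM_NAMES.index(n) for n in free]
    base_arr = x0.as_array()
    lo = np.array([np.log10(bounds.get(n, default_bounds()[n])[0])
                   for n in free])
    hi = np.array([np.log10(bounds.get(n, default_bounds()[n])[1])
                   for n in free])

    history: list[tuple[int, float, float]] = []
    best = {"loss": np.inf, "x": None}
    state = {"n": 0}

    def objective(logx: np.ndarray) -> float:
        if state["n"] >= budget:
            return best["loss"]  # budget spent; freeze
        logx = _project(np.asarray(logx, dtype=float), lo, hi)
        arr = base_arr.copy()
        arr[free_idx] = 10.0 ** logx
        try:
            p = ParameterSet.from_array(arr)
            loss = anchor_loss(p, anchors, **ev_opts)
        except (ValueError, ModelError):
            loss = FAILURE_LOSS
        state["n"] += 1
        if loss < best["loss"]:
            best["loss"], best["x"] = loss, arr.copy()
        history.append((state["n"], loss, best["loss"]))
        if verbose and state["n"] % 25 == 0:
            print(f"[calibrate] eval {state['n']}/{budget} "
                  f"best loss {best['loss']:.6g}", flush=True)
        return loss

    # global phase: deterministic LHS scan of the log box (plus x0 first)
    objective(np.log10(base_arr[free_idx]))
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    pts = qmc.scale(sampler.random(n=n_lhs), lo, hi)
    for k in range(min(n_lhs, max(0, budget - 1))):
        objective(pts[k])

    # local phase: Nelder-Mead from the best point so far
    remaining = budget - state["n"]
    if remaining > len(free) + 1:
        start = np.log10(best["x"][free_idx])
        minimize(
            objective, start, method="Nelder-Mead",
            options={
                "maxfev": remaining, "xatol": 1e-4, "fatol": 1e-10,
                "adaptive": len(free) > 8,
            },
        )

    arr = best["x"] if best["x"] is not None else base_arr
    params = ParameterSet.from_array(arr)
    preds = anchor_predictions(params, anchors, **ev_opts)
    hist = pd.DataFrame(
        history, columns=["eval_index", "loss", "best_loss"])
    return CalibrationResult(
        params=params,
        loss=float(best["loss"]),
        n_evals=state["n"],
        below_tolerance=bool(best["loss"] <= loss_tolerance),
        anchors=anchors,
        predictions=preds,
        history=hist,
    )


def reference_parameters() -> ParameterSet:
    """The bundled reference parameter set.

    Produced by calibrating the model against the printed anchors (see
    ``calibrate`` and ``default_anchors``); it stands in for the original
    supplementary parameter table, which is not redistributed here.
    """
    path = resources.files("gutmuscle").joinpath("data/params_reference.yaml")
    with resources.as_file(path) as p:
        return ParameterSet.from_yaml(p)
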
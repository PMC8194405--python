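"""Summary statistics over simulated trajectories and ensembles.

Fold changes relative to the control steady state, peak extraction, Tukey
boxplot statistics for replicate ensembles, and quadratic least-squares fits
of the intensity -> maximized-muscle-mass relationship with R^2 and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import SPECIES, Trajectory

__all__ = [
    "fold_change_series",
    "peak",
    "BoxStats",
    "boxplot_stats",
    "QuadraticFit",
    "fit_quadratic",
    "fit_quality_average",
    "condition_summary",
]


def fold_change_series(traj: Trajectory, baseline: Sequence[float]) -> Trajectory:
    """Divide every state by the control baseline, component-wise.

    The baseline is the no-exercise steady state; every component must be
    strictly positive for the fold change to be defined.
    """
    base = np.asarray(baseline, dtype=float)
    if base.shape != (len(SPECIES),):
        raise ValueError(f"baseline must have length {len(SPECIES)}")
    if np.any(base <= 0) or not np.all(np.isfinite(base)):
        raise ValueError(
            "invalid baseline: every component must be strictly positive "
            "and finite"
        )
    return replace(traj, states=traj.states / base)


def peak(times: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Global maximum of a sampled series, with its time.

    Ties are broken toward the earliest time (``argmax`` returns the first
    maximal index on the reporting grid).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("empty series")
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("series contains non-finite values")
    i = int(np.argmax(v))
    return float(v[i]), float(t[i])


@dataclass(frozen=True)
class BoxStats:
    """Tukey boxplot statistics of one replicate ensemble."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_stats(values: Sequence[float]) -> BoxStats:
    """Tukey statistics: quartiles by the linear-interpolation quantile rule,
    whiskers at the most extreme data within 1.5*IQR of the quartiles,
    outliers beyond the whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("values contain non-finite entries")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = tuple(sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]))
    return BoxStats(float(med), float(q1), float(q3),
                    whisker_low, whisker_high, outliers)


@dataclass(frozen=True)
class QuadraticFit:
    """Ordinary least-squares quadratic fit y ~ a*x^2 + b*x + c."""

    coef: tuple[float, float, float]  # (quadratic, linear, intercept)
    r2: float
    rmse: float
    n: int

    def predict(self, x: Sequence[float]) -> np.ndarray:
        a, b, c = self.coef
        x = np.asarray(x, dtype=float)
        return a * x**2 + b * x + c


def fit_quadratic(
    x: Sequence[float], y: Sequence[float], *, ddof: int = 0
) -> QuadraticFit:
    """OLS fit of a parabola with coefficient of determination and RMSE.

    ``R^2 = 1 - SS_res/SS_tot`` with ``SS_tot`` about the mean of ``y``;
    ``RMSE = sqrt(SS_res / (n - ddof))``.  The default ``ddof=0`` divides by
    the raw point count (no degrees-of-freedom correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3 or np.unique(x).size < 3:
        raise ValueError("degenerate fit: need at least 3 distinct x values")
    design = np.column_stack([x**2, x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / (n - ddof)))
    return QuadraticFit(tuple(float(c) for c in coef), float(r2), rmse, n)


def fit_quality_average(fits: Iterable[QuadraticFit]) -> tuple[float, float]:
    """Arithmetic mean of (R^2, RMSE) across several fits."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty list of fits")
    return (
        float(np.mean([f.r2 for f in fits])),
        float(np.mean([f.rmse for f in fits])),
    )


def condition_summary(
    fold: Trajectory, label: str = ""
) -> pd.DataFrame:
    """Per-species summary of one fold-change trajectory.

    Columns: species, max_fold, peak_time_h, steady_fold (value at the end
    of the horizon), plus the condition label and intensity.
    """
    rows = []
    for j, name in enumerate(SPECIES):
        v = fold.states[:, j]
        max_fold, t_peak = peak(fold.times, v)
        rows.append(
            {
                "species": name,
                "max_fold": max_fold,
                "peak_time_h": t_peak,
                "steady_fold": float(v[-1]),
                "intensity": fold.intensity,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
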
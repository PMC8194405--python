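"""Basic plots: continuous dynamics, intensity sweeps and ensemble boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from . import experiments  # noqa: E402
from .experiments import ConditionSpec, GridResult  # noqa: E402
from .model import SPECIES, Trajectory  # noqa: E402
from .params import ParameterSet  # noqa: E402

__all__ = ["plot_fold_trajectories", "plot_sweep", "plot_grid_boxes",
           "save_report_plots"]


def plot_fold_trajectories(folds, labels, species: str, ax=None):
    """Fold-change time courses of one species across conditions."""
    if ax is None:
        _, ax = plt.subplots()
    for fold, label in zip(folds, labels):
        ax.plot(fold.times, fold.species(species), label=label)
    ax.set_xlabel("time after stimulus removal (h)")
    ax.set_ylabel(f"{species} fold change")
    ax.legend()
    return ax


def plot_sweep(sweep, ax=None):
    """Maximized muscle fold vs intensity (control entry leftmost)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(sweep.intensities.size), sweep.max_fold,
           tick_label=[f"{s:.2g}" for s in sweep.intensities])
    ax.set_xlabel("exercise intensity (scale)")
    ax.set_ylabel("maximized muscle fold change")
    return ax


def plot_grid_boxes(grid: GridResult, path_stem: Path):
    """One boxplot panel per delay coefficient."""
    for mi, M in enumerate(grid.M_values):
        _, ax = plt.subplots()
        data = [grid.cells[mi][si].values[
            np.isfinite(grid.cells[mi][si].values)]
            for si in range(grid.intensities.size)]
        ax.boxplot(data, tick_labels=[f"{s:.2g}" for s in grid.intensities])
        ax.set_xlabel("exercise intensity (scale)")
        ax.set_ylabel("maximized muscle fold change")
        ax.set_title(f"delay coefficient M = {M:.3g}")
        plt.savefig(f"{path_stem}_M{mi + 1}.png", dpi=120)
        plt.close()


def save_report_plots(
    params: ParameterSet, grid: GridResult, out_dir: str | Path,
    *, hill_orientation: str = "repressive",
) -> None:
    out_dir = Path(out_dir)
    baseline = experiments.control_baseline(
        params, hill_orientation=hill_orientation)
    folds, labels = [], ("low", "moderate", "high")
    for label, s in zip(labels, experiments.LOW_MODERATE_HIGH):
        res = experiments.run_condition(
            params, ConditionSpec(s=s, label=label), baseline=baseline,
            hill_orientation=hill_orientation)
        folds.append(res.fold)
    for species in ("AKT", "mTOR", "SCFAs", "myo"):
        ax = plot_fold_trajectories(folds, labels, species)
        plt.savefig(out_dir / f"dynamics_{species}.png", dpi=120)
        plt.close()
    sweep = experiments.intensity_sweep(
        params, hill_orientation=hill_orientation)
    plot_sweep(sweep)
    plt.savefig(out_dir / "sweep.png", dpi=120)
    plt.close()
    plot_grid_boxes(grid, out_dir / "boxes")
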
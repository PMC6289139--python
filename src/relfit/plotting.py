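"""Waterfall and fit plots."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .problem import EstimationProblem
from .simulate import simulate

__all__ = ["plot_waterfall", "plot_fit"]


def plot_waterfall(waterfalls: dict, threshold: Optional[float] = None,
                   ax=None, path=None):
    """Sorted final objective values per run (``{label: sorted J values}``);
    the standard diagnostic for multi-start convergence."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    best = min(
        (np.min(np.asarray(v)[np.isfinite(v)]) for v in waterfalls.values()
         if np.any(np.isfinite(v))),
        default=None,
    )
    for label, values in waterfalls.items():
        values = np.asarray(values, dtype=float)
        finite = values[np.isfinite(values)]
        ax.plot(np.arange(1, finite.size + 1), np.sort(finite), "o-",
                markersize=3, label=label)
    if best is not None and threshold is not None:
        ax.axhline(best + threshold, color="grey", linestyle="--",
                   linewidth=0.8, label="convergence threshold")
    ax.set_xlabel("sorted start index")
    ax.set_ylabel("negative log-likelihood")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_fit(problem: EstimationProblem, theta: np.ndarray,
             scalings: np.ndarray, path=None):
    """Best-fit observable trajectories overlaid on the (scaled) data.

    Each observable gets a panel; measurements are divided by their group's
    scaling so data and simulation share the model's concentration scale.
    """
    t_grid = np.linspace(problem.unique_times[0] if len(problem.unique_times)
                         else 0.0, problem.unique_times[-1], 200)
    sim = simulate(problem.ode_model, problem.observation_model, theta, t_grid)
    n_y = problem.observation_model.n_observables
    fig, axes = plt.subplots(1, n_y, figsize=(3.2 * n_y, 3.0), squeeze=False)
    names = problem.observation_model.observable_names
    for i, ax in enumerate(axes[0]):
        if sim.ok:
            ax.plot(t_grid, sim.observables[:, i], "-", color="C0",
                    label="model")
        mask = problem.obs_idx == i
        s_rec = scalings[problem.scaling_gidx[mask]]
        ax.plot(problem.rec_times[mask], problem.y[mask] / s_rec, "o",
                markersize=3, color="C3", label="data / s")
        ax.set_title(names[i], fontsize=9)
        ax.set_xlabel("time")
    axes[0][0].set_ylabel("observable")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
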
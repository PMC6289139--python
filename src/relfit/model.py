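"""Model/Results facade over the estimation machinery.

``RelativeDataModel`` is built from data (an :class:`EstimationProblem`, or
its components via :meth:`from_dataframe` / a YAML bundle via
:meth:`from_bundle`); its :meth:`fit` runs multi-start local optimization
and returns a :class:`MultistartResults` carrying the estimates, their
asymptotic standard errors, convergence diagnostics and a ``summary()``
table.  Simulation and plotting hang off these two objects.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import estimation, io
from .estimation import (
    LRT_THRESHOLD,
    MultistartResult,
    free_parameters,
    hierarchical_objective,
    multistart_optimize,
)
from .objectives import negative_log_likelihood
from .problem import EstimationProblem, build_problem, count_parameters
from .simulate import simulate
from .util import central_difference_jacobian

__all__ = ["RelativeDataModel", "MultistartResults"]


class RelativeDataModel:
    """ODE model fitted to relative data by maximum likelihood.

    Parameters
    ----------
    problem : EstimationProblem
        Validated problem (ODE + observation model + measurements +
        scaling/noise parameter structure).
    approach : str
        ``"hierarchical"`` (default): optimize the dynamic parameters only,
        with scalings and noises eliminated analytically at every step.
        ``"standard"``: joint optimization over the full parameter vector.
    """

    def __init__(self, problem: EstimationProblem,
                 approach: str = "hierarchical"):
        if approach not in ("standard", "hierarchical"):
            raise ValueError(f"unknown approach {approach!r}")
        self.problem = problem
        self.approach = approach

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, ode_model, observation_model, measurements,
                       structure, noise_distribution: str = "gaussian",
                       approach: str = "hierarchical") -> "RelativeDataModel":
        """Build from the raw components (validates them)."""
        problem = build_problem(ode_model, observation_model, measurements,
                                structure, noise_distribution)
        return cls(problem, approach=approach)

    @classmethod
    def from_bundle(cls, path, approach: str = "hierarchical") -> "RelativeDataModel":
        """Build from a YAML problem bundle (see :mod:`relfit.io`)."""
        return cls(io.read_problem_bundle(path), approach=approach)

    # ------------------------------------------------------------------
    @property
    def exog_names(self) -> list[str]:
        return [p.name for p in free_parameters(self.problem, self.approach)]

    def objective(self, theta, s=None, sigma=None) -> float:
        """Negative log-likelihood at the given parameters (hierarchical:
        nuisance parameters eliminated unless supplied)."""
        if s is None and sigma is None and self.approach == "hierarchical":
            return hierarchical_objective(self.problem, theta,
                                          with_gradient=False).value
        return negative_log_likelihood(self.problem, theta, s, sigma,
                                       with_gradient=False).value

    def simulate(self, theta, times=None, **kwargs):
        """Forward simulation of the ODE at ``theta``."""
        if times is None:
            times = self.problem.unique_times
        return simulate(self.problem.ode_model,
                        self.problem.observation_model, theta, times, **kwargs)

    def fit(self, n_starts: int = 20, seed: int = 0,
            optimizer_options: Optional[dict] = None,
            start_points: Optional[np.ndarray] = None,
            **kwargs) -> "MultistartResults":
        """Multi-start maximum-likelihood fit; returns results sorted by
        final objective value."""
        run = multistart_optimize(
            self.problem, approach=self.approach, n_starts=n_starts,
            seed=seed, optimizer_options=optimizer_options,
            start_points=start_points, **kwargs,
        )
        return MultistartResults(self, run)


class MultistartResults:
    """Results of a multi-start fit.

    Attributes
    ----------
    params : pandas.Series
        Best full parameter vector: dynamic parameters, then all scaling
        and noise parameters (fixed ones included at their fixed values;
        for the hierarchical approach the measurement parameters are the
        inner-subproblem optima reconstructed at the best theta).
    fun : float
        Best negative log-likelihood.
    """

    def __init__(self, model: RelativeDataModel, run: MultistartResult):
        self.model = model
        self.run = run
        self.problem = model.problem
        best = run.best
        self.theta = best.theta
        self.scalings = best.scalings
        self.noises = best.noises
        self.fun = best.fval
        names = list(self.problem.ode_model.parameter_names)
        values = list(np.atleast_1d(self.theta)) if self.theta is not None else []
        if best.scalings is not None:
            names += [g.group_id for g in self.problem.structure.scaling_groups]
            values += list(best.scalings)
            names += [g.group_id for g in self.problem.structure.noise_groups]
            values += list(best.noises)
        else:
            names = names[: len(values)]
        self.params = pd.Series(values, index=names, name="estimate")
        self._bse: Optional[pd.Series] = None

    # ------------------------------------------------------------------
    @property
    def waterfall(self) -> np.ndarray:
        return self.run.waterfall

    def converged_fraction(self, threshold: float = LRT_THRESHOLD,
                           best: Optional[float] = None) -> float:
        return estimation.converged_fraction(self.run, threshold=threshold,
                                             best=best)

    # ------------------------------------------------------------------
    def _free_gradient(self, x_free: np.ndarray) -> np.ndarray:
        """Gradient of the fitted formulation's objective over its free
        parameters in natural space."""
        problem, approach = self.problem, self.model.approach
        n_theta = problem.n_dynamic
        if approach == "hierarchical":
            res = hierarchical_objective(problem, x_free, with_gradient=True)
        else:
            params = free_parameters(problem, "standard")
            theta = x_free[:n_theta]
            s_free = np.array(
                [v for p, v in zip(params, x_free) if p.block == "s"])
            sig_free = np.array(
                [v for p, v in zip(params, x_free) if p.block == "sigma"])
            res = negative_log_likelihood(problem, theta, s_free, sig_free,
                                          with_gradient=True)
        if res.gradient is None:
            raise RuntimeError("objective not evaluable at the optimum")
        return res.gradient

    def _free_estimates(self) -> np.ndarray:
        params = free_parameters(self.problem, self.model.approach)
        lookup = dict(self.params)
        return np.array([lookup[p.name] for p in params])

    def cov_params(self) -> pd.DataFrame:
        """Asymptotic covariance of the free parameters of the fitted
        formulation: inverse of the finite-difference Hessian of the
        negative log-likelihood at the optimum (pseudo-inverse if
        singular)."""
        params = free_parameters(self.problem, self.model.approach)
        x = self._free_estimates()
        hess = central_difference_jacobian(self._free_gradient, x,
                                           rel_step=1e-5, abs_step=1e-7)
        hess = 0.5 * (hess + hess.T)
        cov = np.linalg.pinv(hess)
        names = [p.name for p in params]
        return pd.DataFrame(cov, index=names, columns=names)

    @property
    def bse(self) -> pd.Series:
        """Standard errors (sqrt of the covariance diagonal; NaN where the
        curvature is not positive)."""
        if self._bse is None:
            try:
                cov = self.cov_params()
                diag = np.diag(cov.values).copy()
                diag[diag < 0] = np.nan
                self._bse = pd.Series(np.sqrt(diag), index=cov.index,
                                      name="std err")
            except Exception:
                names = [p.name for p in
                         free_parameters(self.problem, self.model.approach)]
                self._bse = pd.Series(np.nan, index=names, name="std err")
        return self._bse

    # ------------------------------------------------------------------
    def summary(self, threshold: float = LRT_THRESHOLD) -> str:
        """Human-readable fit report."""
        problem = self.problem
        n_total, n_outer, n_inner = count_parameters(problem)
        frac = self.converged_fraction(threshold)
        lines = [
            "Relative-data ODE maximum-likelihood fit",
            "=" * 58,
            f"approach:            {self.model.approach}",
            f"noise distribution:  {problem.noise_distribution}",
            f"records:             {problem.n_records}",
            f"parameters:          {n_total} total = {n_outer} dynamic"
            f" + {n_inner} measurement",
            f"starts:              {self.run.n_starts} (seed {self.run.seed})",
            f"best -log L:         {self.fun:.6g}",
            f"converged starts:    {frac:.1%} (threshold {threshold:.4g})",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name, value in self.params.items():
            se = bse.get(name, np.nan)
            se_str = f"{se:>12.4g}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<22}{value:>12.5g}{se_str}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_waterfall(self, path=None, threshold: float = LRT_THRESHOLD):
        from .plotting import plot_waterfall
        return plot_waterfall({self.model.approach: self.waterfall},
                              threshold=threshold, path=path)

    def plot_fit(self, path=None):
        from .plotting import plot_fit
        return plot_fit(self.problem, self.theta, self.scalings, path=path)

    def save(self, path, config: Optional[dict] = None):
        """Write a JSON results file (per-start records, waterfall, best
        parameters, seed and config echo)."""
        payload = {
            "approach": self.run.approach,
            "n_starts": self.run.n_starts,
            "best_fval": self.fun,
            "best_parameters": dict(self.params),
            "waterfall": self.waterfall,
            "converged_fraction": self.converged_fraction(),
            "starts": [
                {
                    "index": s.start_index,
                    "fval0": s.fval0,
                    "fval": s.fval,
                    "status": s.status,
                    "n_iterations": s.n_iterations,
                    "wall_time": s.wall_time,
                }
                for s in self.run.starts
            ],
        }
        return io.save_results_json(path, payload, config=config,
                                    seed=self.run.seed)
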
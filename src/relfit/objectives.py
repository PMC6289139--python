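"""Negative log-likelihood objectives for the standard (joint) formulation.

For relative data each measurement is modeled as

    ybar_{i,k} = s_{g(i,k)} * h_i(x(t_k, theta), theta) + eps_{i,k}

with additive Gaussian noise eps ~ N(0, sigma^2) or Laplace noise
eps ~ Laplace(0, sigma).  Observables declared on log10 scale are compared
in log space instead: log10(ybar) = log10(s*h) + eps.

The likelihood (densities use the natural logarithm; "log10" refers only to
the observation scale and the parameter transform) gives the objective

    Gaussian: J = sum 1/2 log(2 pi sigma^2) + (ybar - s*h)^2 / (2 sigma^2)
    Laplace:  J = sum log(2 sigma) + |ybar - s*h| / sigma

Gradients over (theta, free s, free sigma) are exact, using the forward
observable sensitivities for the theta block.  At a Laplace kink
(zero residual) the right-hand derivative in s is returned and the result
is flagged; it is a valid subgradient element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .problem import EstimationProblem
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, SimulationResult, simulate

__all__ = [
    "ObjectiveResult",
    "gaussian_nll",
    "laplace_nll",
    "log10_gaussian_nll",
    "negative_log_likelihood",
    "expand_group_values",
    "free_group_values",
    "SIGMA_FLOOR",
]

LN10 = float(np.log(10.0))

#: floor applied to noise parameters inside the objective; keeps J finite
#: when sigma-hat = 0 arises from noise-free data (flagged in the result)
SIGMA_FLOOR = 1e-10


@dataclass
class ObjectiveResult:
    """Objective value with gradient and evaluation provenance."""

    value: float
    gradient: Optional[np.ndarray] = None
    n_evaluated_residuals: int = 0
    status: str = "ok"
    kink: bool = False
    sigma_floored: bool = False
    simulation: Optional[SimulationResult] = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def expand_group_values(groups, values) -> np.ndarray:
    """Expand free-parameter values to the full per-group array, inserting
    fixed values.  ``values`` may already cover all groups."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    n_free = sum(not g.is_fixed for g in groups)
    if values.size == len(groups):
        full = values.copy()
        for i, g in enumerate(groups):
            if g.is_fixed:
                full[i] = g.fixed_value
        return full
    if values.size == n_free:
        full = np.empty(len(groups))
        it = iter(values)
        for i, g in enumerate(groups):
            full[i] = g.fixed_value if g.is_fixed else next(it)
        return full
    raise ValueError(
        f"expected {n_free} free or {len(groups)} total values, got {values.size}"
    )


def free_group_values(groups, full_values: np.ndarray) -> np.ndarray:
    """Slice the free entries out of a full per-group value array."""
    return np.array(
        [v for g, v in zip(groups, full_values) if not g.is_fixed], dtype=float
    )


def _record_modes(problem: EstimationProblem) -> np.ndarray:
    """Per-record likelihood mode derived from the problem configuration."""
    log10 = problem.record_scale_log10
    if problem.noise_distribution == "laplace":
        if np.any(log10):
            raise NotImplementedError(
                "Laplace noise on log10-scale observables is not supported"
            )
        return np.full(problem.n_records, "laplace_lin")
    return np.where(log10, "gauss_log10", "gauss_lin")


def _evaluate(
    problem: EstimationProblem,
    theta: np.ndarray,
    s: np.ndarray,
    sigma: np.ndarray,
    modes: np.ndarray,
    with_gradient: bool,
    blocks: Sequence[str],
    sim: Optional[SimulationResult],
    atol: float,
    rtol: float,
) -> ObjectiveResult:
    theta = np.asarray(theta, dtype=float)
    s_full = expand_group_values(problem.structure.scaling_groups, s)
    sigma_full = expand_group_values(problem.structure.noise_groups, sigma)
    if np.any(sigma_full < 0):
        raise ValueError("noise parameters must be non-negative")
    floored = bool(np.any(sigma_full < SIGMA_FLOOR))
    sigma_full = np.maximum(sigma_full, SIGMA_FLOOR)

    n_rec = problem.n_records
    if sim is None:
        sim = simulate(
            problem.ode_model,
            problem.observation_model,
            theta,
            problem.unique_times,
            with_sensitivities=with_gradient,
            atol=atol,
            rtol=rtol,
        )
    if not sim.ok:
        return ObjectiveResult(
            value=np.inf, gradient=None, n_evaluated_residuals=0,
            status="solver_failure", simulation=sim,
        )

    h = sim.observables[problem.time_idx, problem.obs_idx]  # (n_rec,)
    if with_gradient:
        dh = sim.observable_sensitivities[problem.time_idx, problem.obs_idx, :]
    else:
        dh = None

    y = problem.y
    s_rec = s_full[problem.scaling_gidx]
    sig_rec = sigma_full[problem.noise_gidx]

    is_lin_g = modes == "gauss_lin"
    is_log_g = modes == "gauss_log10"
    is_lap = modes == "laplace_lin"

    if np.any(is_log_g):
        sh = s_rec * h
        if np.any(sh[is_log_g] <= 0):
            return ObjectiveResult(
                value=np.inf, gradient=None, n_evaluated_residuals=0,
                status="invalid_observable", simulation=sim,
            )

    # residuals per record: linear for gauss_lin/laplace, natural-log-scale
    # handled in log10 units for gauss_log10
    resid = np.empty(n_rec)
    resid[is_lin_g | is_lap] = (y - s_rec * h)[is_lin_g | is_lap]
    if np.any(is_log_g):
        resid[is_log_g] = (np.log10(y) - np.log10(s_rec * h))[is_log_g]

    value = 0.0
    gauss = is_lin_g | is_log_g
    if np.any(gauss):
        value += float(
            np.sum(
                0.5 * np.log(2.0 * np.pi * sig_rec[gauss] ** 2)
                + resid[gauss] ** 2 / (2.0 * sig_rec[gauss] ** 2)
            )
        )
    kink = False
    if np.any(is_lap):
        value += float(
            np.sum(np.log(2.0 * sig_rec[is_lap]) + np.abs(resid[is_lap]) / sig_rec[is_lap])
        )

    gradient = None
    if with_gradient:
        # dresid/dh and dresid/ds per record
        dr_dh = np.zeros(n_rec)
        dr_ds = np.zeros(n_rec)
        dr_dh[is_lin_g | is_lap] = -s_rec[is_lin_g | is_lap]
        dr_ds[is_lin_g | is_lap] = -h[is_lin_g | is_lap]
        if np.any(is_log_g):
            dr_dh[is_log_g] = -1.0 / (h[is_log_g] * LN10)
            dr_ds[is_log_g] = -1.0 / (s_rec[is_log_g] * LN10)

        # dJ/dresid per record
        dJ_dr = np.zeros(n_rec)
        dJ_dr[gauss] = resid[gauss] / sig_rec[gauss] ** 2
        if np.any(is_lap):
            sgn = np.sign(resid)
            at_kink = is_lap & (resid == 0.0)
            if np.any(at_kink):
                kink = True
                # right-hand derivative in s: treat sgn(0) as -sign(h)
                sgn[at_kink] = -np.sign(h[at_kink])
            dJ_dr[is_lap] = sgn[is_lap] / sig_rec[is_lap]

        parts = []
        for block in blocks:
            if block == "theta":
                parts.append((dJ_dr * dr_dh) @ dh)
            elif block == "s":
                per_rec = dJ_dr * dr_ds
                g_s = np.zeros(len(problem.structure.scaling_groups))
                np.add.at(g_s, problem.scaling_gidx, per_rec)
                parts.append(
                    free_group_values(problem.structure.scaling_groups, g_s)
                )
            elif block == "sigma":
                per_rec = np.zeros(n_rec)
                per_rec[gauss] = (
                    1.0 / sig_rec[gauss] - resid[gauss] ** 2 / sig_rec[gauss] ** 3
                )
                per_rec[is_lap] = (
                    1.0 / sig_rec[is_lap]
                    - np.abs(resid[is_lap]) / sig_rec[is_lap] ** 2
                )
                g_n = np.zeros(len(problem.structure.noise_groups))
                np.add.at(g_n, problem.noise_gidx, per_rec)
                parts.append(free_group_values(problem.structure.noise_groups, g_n))
            else:
                raise ValueError(f"unknown gradient block {block!r}")
        gradient = np.concatenate(parts) if parts else np.zeros(0)

    return ObjectiveResult(
        value=value,
        gradient=gradient,
        n_evaluated_residuals=n_rec,
        status="ok",
        kink=kink,
        sigma_floored=floored,
        simulation=sim,
    )


def negative_log_likelihood(
    problem: EstimationProblem,
    theta: np.ndarray,
    s: np.ndarray,
    sigma: np.ndarray,
    with_gradient: bool = True,
    blocks: Sequence[str] = ("theta", "s", "sigma"),
    sim: Optional[SimulationResult] = None,
    atol: float = DEFAULT_ATOL,
    rtol: float = DEFAULT_RTOL,
) -> ObjectiveResult:
    """J(theta, s, sigma) for the problem's configured noise distribution,
    applying each observable's declared scale (linear or log10)."""
    return _evaluate(
        problem, theta, s, sigma, _record_modes(problem), with_gradient,
        blocks, sim, atol, rtol,
    )


def gaussian_nll(problem, theta, s, sigma, with_gradient=True,
                 blocks=("theta", "s", "sigma"), sim=None,
                 atol=DEFAULT_ATOL, rtol=DEFAULT_RTOL) -> ObjectiveResult:
    """Gaussian negative log-likelihood with linear-scale residuals."""
    modes = np.full(problem.n_records, "gauss_lin")
    return _evaluate(problem, theta, s, sigma, modes, with_gradient, blocks,
                     sim, atol, rtol)


def laplace_nll(problem, theta, s, sigma, with_gradient=True,
                blocks=("theta", "s", "sigma"), sim=None,
                atol=DEFAULT_ATOL, rtol=DEFAULT_RTOL) -> ObjectiveResult:
    """Laplace negative log-likelihood (linear scale); robust to outliers."""
    modes = np.full(problem.n_records, "laplace_lin")
    return _evaluate(problem, theta, s, sigma, modes, with_gradient, blocks,
                     sim, atol, rtol)


def log10_gaussian_nll(problem, theta, s, sigma, with_gradient=True,
                       blocks=("theta", "s", "sigma"), sim=None,
                       atol=DEFAULT_ATOL, rtol=DEFAULT_RTOL) -> ObjectiveResult:
    """Gaussian negative log-likelihood on log10 residuals
    (multiplicative noise); requires positive data and positive s*h."""
    if np.any(problem.y <= 0):
        raise ValueError("log10-scale objective requires positive measurements")
    modes = np.full(problem.n_records, "gauss_log10")
    return _evaluate(problem, theta, s, sigma, modes, with_gradient, blocks,
                     sim, atol, rtol)
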
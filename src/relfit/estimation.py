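"""Outer optimization: standard (joint) and hierarchical multi-start fitting.

The standard approach minimizes J over the full vector q = (theta, s, sigma)
jointly.  The hierarchical approach minimizes over theta only, with the
nuisance parameters eliminated by the inner subproblem at every evaluation:

    min_theta J(theta, s-hat(theta), sigma-hat(theta)),
    (s-hat, sigma-hat) = argmin_{s,sigma} J(theta, s, sigma).

Both use multi-start local optimization: start points drawn uniformly on the
optimization (log10-transformed) box, a bound-constrained gradient-based
local optimizer per start, results sorted by final objective value.
Convergence of a start is judged by a likelihood-ratio-style threshold on
the distance of its final objective value to the best value found.

The gradient of the hierarchical objective is the partial derivative of J
with respect to theta at fixed (s-hat, sigma-hat): the inner stationarity
conditions make the indirect terms vanish (exactly for Gaussian noise,
almost everywhere for Laplace).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as sciopt
from scipy.stats import chi2

from .inner import DegenerateGroupError, InnerSolution, observables_per_record, solve_inner
from .objectives import (
    ObjectiveResult,
    expand_group_values,
    negative_log_likelihood,
)
from .problem import EstimationProblem
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, simulate

__all__ = [
    "LRT_THRESHOLD",
    "FreeParameter",
    "StartResult",
    "MultistartResult",
    "ComparisonReport",
    "free_parameters",
    "hierarchical_objective",
    "multistart_optimize",
    "converged_fraction",
    "compare_approaches",
]

#: default convergence threshold in negative-log-likelihood units:
#: half the 0.95 quantile of chi-squared with one degree of freedom
#: (likelihood-ratio test), ~1.9207
LRT_THRESHOLD = float(0.5 * chi2.ppf(0.95, df=1))

_BIG = 1e100  # stands in for +inf inside the optimizer

_DEFAULT_OPTIONS = {"maxiter": 2000, "gtol": 1e-6}


@dataclass
class FreeParameter:
    """One free optimization variable with natural-space bounds and the
    transform used during optimization (lin or log10)."""

    name: str
    lb: float
    ub: float
    scale: str  # "lin" | "log10"
    block: str  # "theta" | "s" | "sigma"

    def to_internal(self, value: float) -> float:
        return float(np.log10(value)) if self.scale == "log10" else float(value)

    def to_natural(self, value: float) -> float:
        return float(10.0 ** value) if self.scale == "log10" else float(value)

    def chain_factor(self, natural: float) -> float:
        """d(natural)/d(internal) for the gradient chain rule."""
        return natural * np.log(10.0) if self.scale == "log10" else 1.0


def free_parameters(problem: EstimationProblem,
                    approach: str) -> list[FreeParameter]:
    """Free parameters of a formulation, in optimizer order:
    dynamic block first, then free scalings, then free noises
    (the latter two only for the standard approach)."""
    if approach not in ("standard", "hierarchical"):
        raise ValueError(f"approach must be standard|hierarchical, got {approach!r}")
    bounds, scales = problem.structure.resolve_dynamic(problem.n_dynamic)
    params = [
        FreeParameter(name, float(lo), float(hi), sc, "theta")
        for name, (lo, hi), sc in zip(
            problem.ode_model.parameter_names, bounds, scales
        )
    ]
    if approach == "standard":
        for g in problem.structure.scaling_groups:
            if not g.is_fixed:
                params.append(FreeParameter(g.group_id, g.lb, g.ub, g.scale, "s"))
        for g in problem.structure.noise_groups:
            if not g.is_fixed:
                params.append(FreeParameter(g.group_id, g.lb, g.ub, g.scale, "sigma"))
    return params


def _to_natural(params: Sequence[FreeParameter], x: np.ndarray) -> np.ndarray:
    return np.array([p.to_natural(v) for p, v in zip(params, x)])


def _to_internal(params: Sequence[FreeParameter], x: np.ndarray) -> np.ndarray:
    return np.array([p.to_internal(v) for p, v in zip(params, x)])


def _chain(params: Sequence[FreeParameter], natural: np.ndarray,
           grad_natural: np.ndarray) -> np.ndarray:
    return grad_natural * np.array(
        [p.chain_factor(v) for p, v in zip(params, natural)]
    )


def hierarchical_objective(
    problem: EstimationProblem,
    theta: np.ndarray,
    with_gradient: bool = True,
    return_inner: bool = False,
    atol: float = DEFAULT_ATOL,
    rtol: float = DEFAULT_RTOL,
):
    """J(theta, s-hat(theta), sigma-hat(theta)) and its theta-gradient.

    Simulates once, solves the inner subproblem on the simulated
    observables, then evaluates the joint objective at the inner optimum.
    The gradient holds (s-hat, sigma-hat) fixed (envelope simplification).
    Simulation failures and degenerate groups yield an infinite value, never
    an exception, so multi-start optimization survives bad draws.
    """
    theta = np.asarray(theta, dtype=float)
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
        res = ObjectiveResult(value=np.inf, gradient=None,
                              n_evaluated_residuals=0,
                              status="solver_failure", simulation=sim)
        return (res, None) if return_inner else res
    h = observables_per_record(problem, sim)
    try:
        inner = solve_inner(problem, h)
    except (DegenerateGroupError, ValueError):
        res = ObjectiveResult(value=np.inf, gradient=None,
                              n_evaluated_residuals=0,
                              status="degenerate_group", simulation=sim)
        return (res, None) if return_inner else res
    res = negative_log_likelihood(
        problem, theta, inner.scalings, inner.noises,
        with_gradient=with_gradient, blocks=("theta",), sim=sim,
        atol=atol, rtol=rtol,
    )
    return (res, inner) if return_inner else res


@dataclass
class StartResult:
    """Outcome of one local optimization start."""

    start_index: int
    x0: np.ndarray  # initial free parameters, natural scale
    x_final: np.ndarray  # final free parameters, natural scale
    fval0: float
    fval: float
    status: str  # "ok" | "failed"
    n_iterations: int
    n_evaluations: int
    wall_time: float
    theta: np.ndarray = None
    scalings: np.ndarray = None  # full per-group arrays
    noises: np.ndarray = None
    inner: Optional[InnerSolution] = field(default=None, repr=False)


@dataclass
class MultistartResult:
    """All starts of a multi-start run, sorted ascending by final J."""

    starts: list[StartResult]
    approach: str
    seed: int
    n_starts: int
    threshold: float = LRT_THRESHOLD
    total_time: float = 0.0

    @property
    def best(self) -> StartResult:
        return self.starts[0]

    @property
    def best_fval(self) -> float:
        return self.starts[0].fval if self.starts else np.inf

    @property
    def waterfall(self) -> np.ndarray:
        """Final objective values sorted ascending (the waterfall vector)."""
        return np.array([s.fval for s in self.starts])

    @property
    def any_ok(self) -> bool:
        return any(s.status == "ok" for s in self.starts)


def converged_fraction(result: MultistartResult,
                       threshold: float = LRT_THRESHOLD,
                       best: Optional[float] = None) -> float:
    """Fraction of starts whose final J lies within ``threshold`` of the
    best value (the run's own best unless ``best`` is given), over all
    performed starts."""
    fvals = result.waterfall
    finite = fvals[np.isfinite(fvals)]
    if finite.size == 0:
        return 0.0
    ref = float(np.min(finite)) if best is None else float(best)
    return float(np.sum(finite <= ref + threshold)) / result.n_starts


def sample_start_points(problem: EstimationProblem, n_starts: int,
                        seed: int) -> np.ndarray:
    """Uniform start points on the transformed box of the *standard*
    (full-q) formulation; shape (n_starts, n_total).

    Hierarchical runs use the theta-block columns of the same array, so the
    two approaches see matched dynamic-parameter starts for a given seed.
    """
    params = free_parameters(problem, "standard")
    lo = np.array([p.to_internal(p.lb) for p in params])
    hi = np.array([p.to_internal(p.ub) for p in params])
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n_starts, len(params)))


def _run_start(problem, params, x0_internal, approach, options,
               atol, rtol) -> tuple:
    """One local optimization; returns (x_final_natural, fval, status,
    n_iter, n_fev)."""
    method = options.get("method", "L-BFGS-B")
    lb = np.array([p.to_internal(p.lb) for p in params])
    ub = np.array([p.to_internal(p.ub) for p in params])
    bounds = list(zip(lb, ub))
    opt = {k: v for k, v in options.items() if k not in ("method",)}
    use_grad = method not in ("Powell", "Nelder-Mead")
    if method == "Powell":
        opt.pop("gtol", None)

    n_theta = problem.n_dynamic

    def split(natural):
        theta = natural[:n_theta]
        s_free = np.array([v for p, v in zip(params, natural) if p.block == "s"])
        sig_free = np.array(
            [v for p, v in zip(params, natural) if p.block == "sigma"]
        )
        return theta, s_free, sig_free

    def fun(x):
        natural = _to_natural(params, x)
        if approach == "hierarchical":
            res = hierarchical_objective(
                problem, natural, with_gradient=use_grad, atol=atol, rtol=rtol
            )
        else:
            theta, s_free, sig_free = split(natural)
            try:
                res = negative_log_likelihood(
                    problem, theta, s_free, sig_free,
                    with_gradient=use_grad, atol=atol, rtol=rtol,
                )
            except ValueError:
                res = ObjectiveResult(value=np.inf, status="domain_error")
        if not np.isfinite(res.value) or res.gradient is None and use_grad:
            if use_grad:
                return _BIG, np.zeros(len(params))
            return _BIG
        if use_grad:
            return res.value, _chain(params, natural, res.gradient)
        return res.value

    try:
        if use_grad:
            sol = sciopt.minimize(fun, x0_internal, jac=True, method=method,
                                  bounds=bounds, options=opt)
        else:
            sol = sciopt.minimize(fun, x0_internal, method=method,
                                  bounds=bounds, options=opt)
        x_fin = np.clip(sol.x, lb, ub)
        fval = float(sol.fun)
        status = "ok" if np.isfinite(fval) and fval < _BIG / 2 else "failed"
        n_iter = int(getattr(sol, "nit", 0))
        n_fev = int(getattr(sol, "nfev", 0))
    except Exception:
        x_fin, fval, status, n_iter, n_fev = x0_internal, np.inf, "failed", 0, 0
    return _to_natural(params, x_fin), fval, status, n_iter, n_fev


def multistart_optimize(
    problem: EstimationProblem,
    approach: str = "hierarchical",
    n_starts: int = 20,
    seed: int = 0,
    optimizer_options: Optional[dict] = None,
    start_points: Optional[np.ndarray] = None,
    atol: float = DEFAULT_ATOL,
    rtol: float = DEFAULT_RTOL,
) -> MultistartResult:
    """Multi-start local optimization of the chosen formulation.

    Start points are sampled uniformly on the transformed (log10) box with
    the given seed; ``start_points`` (full-q internal coordinates, e.g. from
    :func:`sample_start_points`) overrides the sampling so runs can be
    matched across approaches.  Each start runs a bound-constrained local
    optimizer (default L-BFGS-B with analytic gradients; set
    ``optimizer_options={"method": "Powell"}`` for a gradient-free fallback,
    useful under Laplace noise where the objective has kinks).

    For the hierarchical approach the optimal scalings and noises are
    reconstructed at each start's final theta, so both approaches report
    full parameter vectors.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    options = dict(_DEFAULT_OPTIONS)
    options.update(optimizer_options or {})

    params_std = free_parameters(problem, "standard")
    params = free_parameters(problem, approach)
    if start_points is None:
        start_points = sample_start_points(problem, n_starts, seed)
    starts_internal = np.asarray(start_points, dtype=float)
    if starts_internal.shape != (n_starts, len(params_std)):
        raise ValueError("start_points shape must be (n_starts, n_total)")
    if approach == "hierarchical":
        starts_internal = starts_internal[:, : problem.n_dynamic]

    n_theta = problem.n_dynamic
    results: list[StartResult] = []
    t_all0 = time.perf_counter()
    for i in range(n_starts):
        x0_int = starts_internal[i]
        x0_nat = _to_natural(params, x0_int)
        t0 = time.perf_counter()
        # initial objective value (cheap bookkeeping, no gradient)
        fval0 = _start_value(problem, params, x0_nat, approach, atol, rtol)
        x_fin, fval, status, n_iter, n_fev = _run_start(
            problem, params, x0_int, approach, options, atol, rtol
        )
        elapsed = time.perf_counter() - t0

        theta = x_fin[:n_theta]
        inner = None
        if status == "ok":
            if approach == "hierarchical":
                res, inner = hierarchical_objective(
                    problem, theta, with_gradient=False, return_inner=True,
                    atol=atol, rtol=rtol,
                )
                fval = res.value if np.isfinite(res.value) else fval
                if inner is not None:
                    s_full, sig_full = inner.scalings, inner.noises
                else:
                    s_full = sig_full = None
                    status = "failed"
                    fval = np.inf
            else:
                s_free = np.array(
                    [v for p, v in zip(params, x_fin) if p.block == "s"]
                )
                sig_free = np.array(
                    [v for p, v in zip(params, x_fin) if p.block == "sigma"]
                )
                s_full = expand_group_values(
                    problem.structure.scaling_groups, s_free
                )
                sig_full = expand_group_values(
                    problem.structure.noise_groups, sig_free
                )
        else:
            s_full = sig_full = None
            fval = np.inf
        results.append(
            StartResult(
                start_index=i,
                x0=x0_nat,
                x_final=x_fin,
                fval0=fval0,
                fval=float(fval),
                status=status,
                n_iterations=n_iter,
                n_evaluations=n_fev,
                wall_time=elapsed,
                theta=theta,
                scalings=s_full,
                noises=sig_full,
                inner=inner,
            )
        )
    total = time.perf_counter() - t_all0

    results.sort(key=lambda s: (not np.isfinite(s.fval), s.fval))
    return MultistartResult(
        starts=results,
        approach=approach,
        seed=seed,
        n_starts=n_starts,
        total_time=total,
    )


def _start_value(problem, params, x_nat, approach, atol, rtol) -> float:
    try:
        if approach == "hierarchical":
            res = hierarchical_objective(
                problem, x_nat[: problem.n_dynamic], with_gradient=False,
                atol=atol, rtol=rtol,
            )
        else:
            theta = x_nat[: problem.n_dynamic]
            s_free = np.array([v for p, v in zip(params, x_nat) if p.block == "s"])
            sig_free = np.array(
                [v for p, v in zip(params, x_nat) if p.block == "sigma"]
            )
            res = negative_log_likelihood(
                problem, theta, s_free, sig_free, with_gradient=False,
                atol=atol, rtol=rtol,
            )
        return float(res.value)
    except ValueError:
        return np.inf


@dataclass
class ComparisonReport:
    """Standard-vs-hierarchical comparison on one problem with matched
    start points."""

    fractions: dict  # approach -> converged fraction
    best_fval: dict  # approach -> best final J
    cpu_per_converged: dict  # approach -> total time / n converged (inf if none)
    waterfalls: dict  # approach -> sorted final J list
    n_starts: int
    seed: int
    threshold: float
    results: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for f in self.fractions.values():
            if not (0.0 <= f <= 1.0):
                raise ValueError("converged fraction outside [0, 1]")


def compare_approaches(
    problem: EstimationProblem,
    n_starts: int = 20,
    seed: int = 0,
    optimizer_options: Optional[dict] = None,
    threshold: float = LRT_THRESHOLD,
    atol: float = DEFAULT_ATOL,
    rtol: float = DEFAULT_RTOL,
) -> ComparisonReport:
    """Run both approaches with matched start points and compare.

    The hierarchical runs reuse the theta block of the standard start
    points, so the comparison isolates the effect of eliminating the
    nuisance parameters.  Convergence of each start is judged against the
    pooled best objective value across both approaches.
    """
    start_points = sample_start_points(problem, n_starts, seed)
    runs = {
        approach: multistart_optimize(
            problem, approach=approach, n_starts=n_starts, seed=seed,
            optimizer_options=optimizer_options, start_points=start_points,
            atol=atol, rtol=rtol,
        )
        for approach in ("standard", "hierarchical")
    }
    finite_bests = [r.best_fval for r in runs.values() if np.isfinite(r.best_fval)]
    pooled_best = min(finite_bests) if finite_bests else np.inf
    fractions = {}
    cpu = {}
    for name, run in runs.items():
        frac = converged_fraction(run, threshold=threshold, best=pooled_best)
        fractions[name] = frac
        n_conv = frac * n_starts
        cpu[name] = run.total_time / n_conv if n_conv > 0 else np.inf
    return ComparisonReport(
        fractions=fractions,
        best_fval={k: r.best_fval for k, r in runs.items()},
        cpu_per_converged=cpu,
        waterfalls={k: r.waterfall.tolist() for k, r in runs.items()},
        n_starts=n_starts,
        seed=seed,
        threshold=threshold,
        results=runs,
    )
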
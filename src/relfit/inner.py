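"""Inner subproblem: conditionally optimal scaling and noise parameters.

Given the simulated observables h_{i,k} at fixed dynamic parameters theta,
the scaling parameters s and noise parameters sigma that minimize the
negative log-likelihood have closed forms:

Gaussian, linear scale (per group, sums over the group's records):

    s-hat      = sum(ybar * h) / sum(h^2)
    sigma-hat^2 = mean((ybar - s-hat * h)^2)

Gaussian, log10 scale:

    log10 s-hat = mean(log10 ybar - log10 h)
    sigma-hat^2 = mean((log10 ybar - log10 h - log10 s-hat)^2)

Laplace: the objective is piecewise linear in s with kinks at the jump
points s_{i,k} = ybar/h; its derivative is

    dJ/ds = -(1/sigma) * sum(|h| * sgn(ybar/h - s)),

so s-hat is found by sorting the jump points and checking the derivative
sign on the segments between them (equivalently, s-hat is the |h|-weighted
median of the ratios ybar/h), and

    sigma-hat = mean(|h| * |ybar/h - s-hat|) = mean(|ybar - s-hat * h|).

None of this requires integrating the ODE again — the whole point of the
hierarchical reformulation.

When a scaling group and a noise group overlap only partially (e.g. one
scaling shared across observables that keep distinct unknown noises), the
per-group formulas couple; those connected components are solved by
coordinate descent over exact block updates (precision-weighted means /
medians), which decreases the objective monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .objectives import LN10, SIGMA_FLOOR
from .problem import EstimationProblem
from .simulate import SimulationResult

__all__ = [
    "InnerSolution",
    "DegenerateGroupError",
    "gaussian_inner",
    "laplace_inner_scaling",
    "laplace_inner_noise",
    "log10_gaussian_inner",
    "solve_inner",
    "observables_per_record",
]

_CD_TOL = 1e-10
_CD_MAX_ITER = 100


class DegenerateGroupError(ValueError):
    """All simulated observables vanish within a group: its scaling
    parameter is unidentifiable at this theta."""


@dataclass
class InnerSolution:
    """Optimal scaling/noise parameters (full per-group arrays, fixed
    groups carrying their fixed values) plus diagnostics."""

    scalings: np.ndarray
    noises: np.ndarray
    method_used: str
    jump_points: Optional[np.ndarray] = None
    iterations: int = 0
    scaling_ids: list = field(default_factory=list)
    noise_ids: list = field(default_factory=list)

    def scaling_by_id(self) -> dict:
        return dict(zip(self.scaling_ids, self.scalings))

    def noise_by_id(self) -> dict:
        return dict(zip(self.noise_ids, self.noises))


# ---------------------------------------------------------------------------
# per-group closed forms
# ---------------------------------------------------------------------------


def gaussian_inner(h_values: np.ndarray, y_values: np.ndarray) -> tuple[float, float]:
    """Closed-form (s-hat, sigma-hat^2) for one Gaussian linear-scale group."""
    h = np.asarray(h_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    denom = float(np.sum(h * h))
    if denom == 0.0:
        raise DegenerateGroupError("all simulated observables are zero in group")
    s_hat = float(np.sum(y * h)) / denom
    sigma2 = float(np.mean((y - s_hat * h) ** 2))
    return s_hat, sigma2


def laplace_inner_scaling(h_values: np.ndarray, y_values: np.ndarray,
                          weights: Optional[np.ndarray] = None) -> float:
    """Kink-search for the optimal Laplace scaling of one group.

    Jump points ybar/h are sorted and the derivative sign is checked on the
    segments between them; records with h = 0 contribute no jump point
    (their |h|*sgn term vanishes identically).  If the derivative is exactly
    zero on a segment the lower adjacent jump point is returned — any point
    of the flat segment is optimal.  ``weights`` (default |h|) allows the
    precision-weighted variant |h|/sigma used for coupled groups.
    """
    h = np.asarray(h_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    nz = h != 0.0
    if not np.any(nz):
        raise DegenerateGroupError("all simulated observables are zero in group")
    ratios = y[nz] / h[nz]
    w = np.abs(h[nz]) if weights is None else np.asarray(weights, dtype=float)[nz]
    order = np.argsort(ratios, kind="stable")
    ratios = ratios[order]
    w = w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    # derivative just right of jump j is proportional to 2*cum_j - total;
    # the minimizer is the first jump where it becomes >= 0 (== 0: flat
    # segment, lower adjacent point returned)
    j = int(np.searchsorted(2.0 * cum - total, 0.0, side="left"))
    return float(ratios[j])


def laplace_inner_noise(h_values: np.ndarray, y_values: np.ndarray,
                        s_hat: float) -> float:
    """Mean absolute residual: the optimal Laplace scale given s-hat.

    Uses |h|*|ybar/h - s| = |ybar - s*h| (also valid at h = 0, where the
    record contributes |ybar|)."""
    h = np.asarray(h_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    return float(np.mean(np.abs(y - s_hat * h)))


def log10_gaussian_inner(h_values: np.ndarray,
                         y_values: np.ndarray) -> tuple[float, float]:
    """Closed-form (s-hat, sigma-hat^2) for one Gaussian log10-scale group.

    sigma-hat^2 is in log10 units, matching the log-residual objective."""
    h = np.asarray(h_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if np.any(h <= 0) or np.any(y <= 0):
        raise ValueError("log10-scale inner solution requires positive h and ybar")
    d = np.log10(y) - np.log10(h)
    log_s = float(np.mean(d))
    sigma2 = float(np.mean((d - log_s) ** 2))
    return 10.0 ** log_s, sigma2


# ---------------------------------------------------------------------------
# dispatch over the grouping structure
# ---------------------------------------------------------------------------


def observables_per_record(problem: EstimationProblem,
                           sim: SimulationResult) -> np.ndarray:
    """Simulated observable value h for every measurement record."""
    return sim.observables[problem.time_idx, problem.obs_idx]


def _components(problem: EstimationProblem) -> list[tuple[list[int], list[int]]]:
    """Connected components of the bipartite scaling-group/noise-group graph
    (edges: a record shared by both groups)."""
    n_s = len(problem.structure.scaling_groups)
    n_n = len(problem.structure.noise_groups)
    parent = list(range(n_s + n_n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for sg, ng in zip(problem.scaling_gidx, problem.noise_gidx):
        union(int(sg), n_s + int(ng))

    comps: dict[int, tuple[list[int], list[int]]] = {}
    for i in range(n_s):
        comps.setdefault(find(i), ([], []))[0].append(i)
    for j in range(n_n):
        comps.setdefault(find(n_s + j), ([], []))[1].append(j)
    return list(comps.values())


def _group_mode(problem: EstimationProblem, records: np.ndarray) -> str:
    if problem.noise_distribution == "laplace":
        return "laplace"
    return "log10" if problem.record_scale_log10[records[0]] else "linear"


def _analytic_single(problem, s_grp, n_grp, h, y, mode):
    """Solve one uncoupled (single scaling group, single noise group)
    component, honoring fixed parameters."""
    if mode == "linear":
        if s_grp.is_fixed:
            s_hat = s_grp.fixed_value
        else:
            s_hat = gaussian_inner(h, y)[0]
        if n_grp.is_fixed:
            sigma_hat = n_grp.fixed_value
        else:
            sigma_hat = float(np.sqrt(np.mean((y - s_hat * h) ** 2)))
        return s_hat, sigma_hat, None
    if mode == "log10":
        if s_grp.is_fixed:
            s_hat = s_grp.fixed_value
            if np.any(h <= 0) or np.any(y <= 0):
                raise ValueError("log10-scale group requires positive h and ybar")
        else:
            s_hat = log10_gaussian_inner(h, y)[0]
        if n_grp.is_fixed:
            sigma_hat = n_grp.fixed_value
        else:
            r = np.log10(y) - np.log10(s_hat * h)
            sigma_hat = float(np.sqrt(np.mean(r * r)))
        return s_hat, sigma_hat, None
    # laplace
    jumps = None
    if s_grp.is_fixed:
        s_hat = s_grp.fixed_value
    else:
        s_hat = laplace_inner_scaling(h, y)
        nz = h != 0.0
        jumps = np.sort(y[nz] / h[nz])
    if n_grp.is_fixed:
        sigma_hat = n_grp.fixed_value
    else:
        sigma_hat = laplace_inner_noise(h, y, s_hat)
    return s_hat, sigma_hat, jumps


def _component_objective(problem, recs, h, y, s_full, sigma_full) -> float:
    """Objective restricted to one component's records (no simulation)."""
    s_rec = s_full[problem.scaling_gidx[recs]]
    sig = np.maximum(sigma_full[problem.noise_gidx[recs]], SIGMA_FLOOR)
    if problem.noise_distribution == "laplace":
        return float(np.sum(np.log(2.0 * sig) + np.abs(y - s_rec * h) / sig))
    log10 = problem.record_scale_log10[recs]
    r = np.where(log10, np.log10(np.abs(y)) - np.log10(np.abs(s_rec * h)),
                 y - s_rec * h)
    return float(np.sum(0.5 * np.log(2 * np.pi * sig**2) + r**2 / (2 * sig**2)))


def _coordinate_descent(problem, comp, s_full, sigma_full, h_all) -> int:
    """Exact block updates for a coupled component; monotone by construction.

    Returns the iteration count.  On a (theoretically impossible) objective
    increase in a Laplace s-update, that update is replaced by a 1-D scan
    over the group's jump points.
    """
    s_groups = problem.structure.scaling_groups
    n_groups = problem.structure.noise_groups
    s_idx, n_idx = comp
    recs = np.nonzero(np.isin(problem.scaling_gidx, s_idx))[0]
    h = h_all[recs]
    y = problem.y[recs]

    # neutral starting values; the first block sweep replaces them with
    # exact conditional optima
    for g in s_idx:
        if not s_groups[g].is_fixed and not np.isfinite(s_full[g]):
            s_full[g] = 1.0
    for j in n_idx:
        if not n_groups[j].is_fixed and sigma_full[j] <= 0:
            sigma_full[j] = 1.0

    J = _component_objective(problem, recs, h, y, s_full, sigma_full)
    laplace = problem.noise_distribution == "laplace"
    for it in range(1, _CD_MAX_ITER + 1):
        for g in s_idx:
            grp = s_groups[g]
            if grp.is_fixed:
                continue
            in_g = problem.scaling_gidx[recs] == g
            hg, yg = h[in_g], y[in_g]
            sig_g = np.maximum(
                sigma_full[problem.noise_gidx[recs][in_g]], SIGMA_FLOOR
            )
            if laplace:
                s_new = laplace_inner_scaling(hg, yg, weights=np.abs(hg) / sig_g)
            elif problem.record_scale_log10[recs[in_g][0]]:
                w = 1.0 / sig_g**2
                s_new = 10.0 ** (
                    float(np.sum(w * (np.log10(yg) - np.log10(hg)))) / float(np.sum(w))
                )
            else:
                denom = float(np.sum(hg * hg / sig_g**2))
                if denom == 0.0:
                    raise DegenerateGroupError(
                        f"all simulated observables are zero in group {grp.group_id!r}"
                    )
                s_new = float(np.sum(yg * hg / sig_g**2)) / denom
            old = s_full[g]
            s_full[g] = s_new
            if laplace:
                J_new = _component_objective(problem, recs, h, y, s_full, sigma_full)
                if J_new > J + 1e-9:  # safety net; block update is exact
                    best = (J, old)
                    for cand in np.unique(yg[hg != 0] / hg[hg != 0]):
                        s_full[g] = cand
                        Jc = _component_objective(problem, recs, h, y,
                                                  s_full, sigma_full)
                        if Jc < best[0]:
                            best = (Jc, cand)
                    s_full[g] = best[1]
        for j in n_idx:
            grp = n_groups[j]
            if grp.is_fixed:
                continue
            in_j = problem.noise_gidx[recs] == j
            hj, yj = h[in_j], y[in_j]
            s_rec = s_full[problem.scaling_gidx[recs][in_j]]
            if laplace:
                sigma_full[j] = float(np.mean(np.abs(yj - s_rec * hj)))
            elif problem.record_scale_log10[recs[in_j][0]]:
                r = np.log10(yj) - np.log10(s_rec * hj)
                sigma_full[j] = float(np.sqrt(np.mean(r * r)))
            else:
                sigma_full[j] = float(np.sqrt(np.mean((yj - s_rec * hj) ** 2)))
        J_new = _component_objective(problem, recs, h, y, s_full, sigma_full)
        if J - J_new < _CD_TOL:
            return it
        J = J_new
    return _CD_MAX_ITER


def solve_inner(
    problem: EstimationProblem,
    simulated_observables: np.ndarray,
    theta: Optional[np.ndarray] = None,
) -> InnerSolution:
    """Optimal (s-hat, sigma-hat) for all groups given per-record simulated
    observables.  Never integrates the ODE.

    ``simulated_observables`` is the per-record h array (see
    :func:`observables_per_record`).  Uncoupled components (one scaling and
    one noise group over the same records) are solved analytically; coupled
    components by coordinate descent with exact block updates.
    """
    h_all = np.asarray(simulated_observables, dtype=float)
    if h_all.shape != (problem.n_records,):
        raise ValueError("simulated_observables must be a per-record array")

    s_groups = problem.structure.scaling_groups
    n_groups = problem.structure.noise_groups
    s_full = np.array(
        [g.fixed_value if g.is_fixed else np.nan for g in s_groups], dtype=float
    )
    sigma_full = np.array(
        [g.fixed_value if g.is_fixed else -1.0 for g in n_groups], dtype=float
    )

    jump_points: list[np.ndarray] = []
    iterations = 0
    any_coupled = False

    for comp in _components(problem):
        s_idx, n_idx = comp
        if len(s_idx) == 1 and len(n_idx) == 1:
            g, j = s_idx[0], n_idx[0]
            recs = problem.records_in_scaling_group(g)
            h, y = h_all[recs], problem.y[recs]
            mode = _group_mode(problem, recs)
            try:
                s_hat, sigma_hat, jumps = _analytic_single(
                    problem, s_groups[g], n_groups[j], h, y, mode
                )
            except DegenerateGroupError as err:
                raise DegenerateGroupError(
                    f"group {s_groups[g].group_id!r}: {err}"
                ) from None
            s_full[g] = s_hat
            sigma_full[j] = sigma_hat
            if jumps is not None:
                jump_points.append(jumps)
        else:
            any_coupled = True
            iterations = max(
                iterations,
                _coordinate_descent(problem, comp, s_full, sigma_full, h_all),
            )

    if any_coupled:
        method = "coordinate_descent"
    elif problem.noise_distribution == "laplace":
        method = "laplace_kinksearch"
    elif np.all(problem.record_scale_log10):
        method = "log10_gaussian_analytic"
    else:
        method = "gaussian_analytic"

    return InnerSolution(
        scalings=s_full,
        noises=sigma_full,
        method_used=method,
        jump_points=np.sort(np.concatenate(jump_points)) if jump_points else None,
        iterations=iterations,
        scaling_ids=[g.group_id for g in s_groups],
        noise_ids=[g.group_id for g in n_groups],
    )
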
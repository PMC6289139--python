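"""Validation studies: oracle comparisons, agreement, convergence, recovery.

These are the package's quantitative self-checks, run by the test suite and
the reproduction script.  Each study generates its own synthetic inputs
from a seed and recomputes its quantities from scratch:

* :func:`inner_oracle_study` — closed-form/kink-search inner solutions vs
  an independent dense-grid + simplex-refinement oracle over (s, sigma);
* :func:`stationarity_study` — Gaussian inner stationarity and the
  envelope identity of the hierarchical gradient;
* :func:`optimum_identity_study` — closed-form objective identities at the
  inner optimum;
* :func:`approach_agreement_study` — best objective value of standard vs
  hierarchical multi-starts on matched start points;
* :func:`convergence_study` — fraction of converged starts per approach,
  replicated over seeds;
* :func:`recovery_study` — recovery of the generating dynamic and scaling
  parameters on the cascade benchmark.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize as sciopt

from .estimation import (
    compare_approaches,
    hierarchical_objective,
    multistart_optimize,
)
from .inner import (
    gaussian_inner,
    laplace_inner_noise,
    laplace_inner_scaling,
    log10_gaussian_inner,
    observables_per_record,
    solve_inner,
)
from .objectives import SIGMA_FLOOR
from .simulate import simulate
from .synthetic import SyntheticProblemSpec, benchmark_suite, generate_problem
from .util import central_difference_gradient

__all__ = [
    "inner_oracle_study",
    "stationarity_study",
    "optimum_identity_study",
    "approach_agreement_study",
    "convergence_study",
    "recovery_study",
]

_CONFIGS = ("gaussian_linear", "gaussian_log10", "laplace")


def _group_J(h, y, s, sigma, config):
    """Single-group objective, the quantity both solver and oracle minimize."""
    sigma = max(float(sigma), SIGMA_FLOOR)
    if config == "laplace":
        return float(np.sum(np.log(2 * sigma) + np.abs(y - s * h) / sigma))
    if config == "gaussian_log10":
        r = np.log10(y) - np.log10(s * h)
    else:
        r = y - s * h
    return float(np.sum(0.5 * np.log(2 * np.pi * sigma**2)
                        + r**2 / (2 * sigma**2)))


def _grid_oracle(h, y, config, n_grid=80):
    """Dense (s, sigma) grid followed by Nelder-Mead refinement.

    Independent of the closed forms: brute minimization of the same
    objective."""
    ratios = y[h != 0] / h[h != 0]
    if config == "gaussian_log10":
        s_grid = np.geomspace(max(np.min(ratios) * 0.5, 1e-6),
                              np.max(ratios) * 2.0, n_grid)
    else:
        span = np.max(ratios) - np.min(ratios) + 1.0
        s_grid = np.linspace(np.min(ratios) - 0.1 * span,
                             np.max(ratios) + 0.1 * span, n_grid)
    sig_grid = np.geomspace(1e-6, 10.0, n_grid)

    # vectorized J over the grid
    if config == "laplace":
        sar = np.abs(y[None, :] - s_grid[:, None] * h[None, :]).sum(axis=1)
        J = (len(y) * np.log(2 * sig_grid)[None, :]
             + sar[:, None] / sig_grid[None, :])
    else:
        if config == "gaussian_log10":
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.log10(y[None, :]) - np.log10(
                    s_grid[:, None] * h[None, :])
        else:
            r = y[None, :] - s_grid[:, None] * h[None, :]
        ssr = np.nansum(r**2, axis=1)
        J = (len(y) * 0.5 * np.log(2 * np.pi * sig_grid**2)[None, :]
             + ssr[:, None] / (2 * sig_grid**2)[None, :])
    J = np.where(np.isfinite(J), J, np.inf)
    i, j = np.unravel_index(np.argmin(J), J.shape)

    res = sciopt.minimize(
        lambda p: _group_J(h, y, p[0], abs(p[1]), config),
        np.array([s_grid[i], sig_grid[j]]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    return min(float(J[i, j]), float(res.fun))


def _random_instance(rng, config):
    n = int(rng.integers(1, 51))
    if config == "gaussian_log10":
        h = rng.lognormal(0.0, 1.0, n)
        y = rng.lognormal(0.5, 1.0, n)
    else:
        h = rng.normal(1.0, 1.0, n)
        h[np.abs(h) < 1e-6] = 1e-3
        y = 2.0 * h + rng.normal(0.0, 0.5, n)
    return h, y


def _solve_instance(h, y, config):
    if config == "laplace":
        s_hat = laplace_inner_scaling(h, y)
        sig_hat = laplace_inner_noise(h, y, s_hat)
    elif config == "gaussian_log10":
        s_hat, sig2 = log10_gaussian_inner(h, y)
        sig_hat = float(np.sqrt(sig2))
    else:
        s_hat, sig2 = gaussian_inner(h, y)
        sig_hat = float(np.sqrt(sig2))
    return s_hat, sig_hat


def inner_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    """Compare the analytic inner solutions with the grid oracle.

    Returns the worst signed relative excess (J_analytic - J_oracle) /
    (1 + |J_oracle|) per configuration; negative or tiny values mean the
    closed form is at least as good as brute-force minimization.
    """
    rng = np.random.default_rng(seed)
    gaps = {}
    for config in _CONFIGS:
        worst = -np.inf
        for _ in range(n_instances):
            h, y = _random_instance(rng, config)
            s_hat, sig_hat = _solve_instance(h, y, config)
            J_solver = _group_J(h, y, s_hat, sig_hat, config)
            J_oracle = _grid_oracle(h, y, config)
            gap = (J_solver - J_oracle) / (1.0 + abs(J_oracle))
            worst = max(worst, gap)
        gaps[config] = worst
    gaps["max"] = max(gaps.values())
    gaps["n_instances"] = n_instances
    return gaps


def stationarity_study(n_instances: int = 200, n_theta: int = 20,
                       seed: int = 0) -> dict:
    """Gaussian inner stationarity and the envelope-gradient identity.

    * ``max_stationarity``: largest relative (s, sigma) gradient norm of
      the per-group Gaussian objective at the closed-form optimum.
    * ``max_envelope_err``: largest relative error between the analytic
      theta-gradient of the hierarchical objective and central finite
      differences, over random theta of the conversion-reaction problem.
    """
    rng = np.random.default_rng(seed)
    worst_stat = 0.0
    for _ in range(n_instances):
        h, y = _random_instance(rng, "gaussian_linear")
        s_hat, sig_hat = _solve_instance(h, y, "gaussian_linear")
        if sig_hat < 1e-8:  # exactly proportional draw; gradient trivially 0
            continue
        grad = central_difference_gradient(
            lambda p: _group_J(h, y, p[0], p[1], "gaussian_linear"),
            np.array([s_hat, sig_hat]), rel_step=1e-7,
        )
        ref = max(1.0, abs(_group_J(h, y, s_hat, sig_hat, "gaussian_linear")))
        worst_stat = max(worst_stat, float(np.max(np.abs(grad))) / ref)

    spec = SyntheticProblemSpec(topology="conversion_reaction", n_times=10,
                                seed=seed)
    problem, truth = generate_problem(spec)
    tight = dict(atol=1e-12, rtol=1e-10)
    worst_env = 0.0
    for _ in range(n_theta):
        theta = truth.theta * 10 ** rng.uniform(-0.3, 0.3, truth.theta.size)
        res = hierarchical_objective(problem, theta, **tight)
        fd = central_difference_gradient(
            lambda q: hierarchical_objective(problem, q, with_gradient=False,
                                             **tight).value,
            theta, rel_step=1e-6,
        )
        err = np.max(np.abs(res.gradient - fd) / (1.0 + np.abs(fd)))
        worst_env = max(worst_env, float(err))
    return {
        "max_stationarity": worst_stat,
        "max_envelope_err": worst_env,
        "n_instances": n_instances,
        "n_theta": n_theta,
    }


def optimum_identity_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Closed-form objective identities at the inner optimum.

    Gaussian: J = sum_g (n_g/2)(log(2 pi sigma_g^2) + 1);
    Laplace:  J = sum_g n_g (log(2 sigma_g) + 1).
    Returns the worst relative deviation for each.
    """
    rng = np.random.default_rng(seed)
    worst = {"gaussian": 0.0, "laplace": 0.0}
    for _ in range(n_instances):
        for config, key in (("gaussian_linear", "gaussian"),
                            ("laplace", "laplace")):
            h, y = _random_instance(rng, config)
            n = len(y)
            s_hat, sig_hat = _solve_instance(h, y, config)
            if sig_hat < 1e-12:
                continue
            J = _group_J(h, y, s_hat, sig_hat, config)
            if key == "gaussian":
                J_closed = 0.5 * n * (np.log(2 * np.pi * sig_hat**2) + 1.0)
            else:
                J_closed = n * (np.log(2 * sig_hat) + 1.0)
            dev = abs(J - J_closed) / (1.0 + abs(J_closed))
            worst[key] = max(worst[key], float(dev))
    worst["n_instances"] = n_instances
    return worst


def approach_agreement_study(seed: int = 0, n_starts: int = 50) -> dict:
    """|best J_hierarchical - best J_standard| on matched multi-starts for
    the conversion-reaction and cascade benchmark problems."""
    out = {}
    for key, topology in (("conversion_reaction", "conversion_reaction"),
                          ("cascade3", "cascade3")):
        spec = SyntheticProblemSpec(topology=topology,
                                    grouping="per_observable", seed=seed + 42)
        problem, _ = generate_problem(spec)
        cmp = compare_approaches(problem, n_starts=n_starts, seed=seed + 7)
        out[key] = {
            "gap": abs(cmp.best_fval["hierarchical"]
                       - cmp.best_fval["standard"]),
            "best_hierarchical": cmp.best_fval["hierarchical"],
            "best_standard": cmp.best_fval["standard"],
            "n_starts": n_starts,
        }
    return out


def convergence_study(n_replicates: int = 10, n_starts: int = 16,
                      seed: int = 0) -> dict:
    """Converged-start fractions per approach over seeded replicates of the
    benchmark suite; a replicate is a hierarchical 'win' when its pooled
    fraction is at least the standard approach's."""
    wins = 0
    frac_h, frac_s = [], []
    for rep in range(n_replicates):
        fh, fs = [], []
        for spec in benchmark_suite(seed + 100 * rep):
            problem, _ = generate_problem(spec)
            cmp = compare_approaches(problem, n_starts=n_starts,
                                     seed=seed + 10 * rep)
            fh.append(cmp.fractions["hierarchical"])
            fs.append(cmp.fractions["standard"])
        frac_h.append(float(np.mean(fh)))
        frac_s.append(float(np.mean(fs)))
        if frac_h[-1] >= frac_s[-1]:
            wins += 1
    return {
        "wins": wins,
        "n_replicates": n_replicates,
        "mean_fraction_hierarchical": float(np.mean(frac_h)),
        "mean_fraction_standard": float(np.mean(frac_s)),
        "fractions_hierarchical": frac_h,
        "fractions_standard": frac_s,
    }


def recovery_study(n_seeds: int = 10, n_starts: int = 20,
                   seed: int = 0) -> dict:
    """Parameter recovery on the cascade benchmark (Gaussian noise at 10%
    of the signal, 20 time points).

    Fits each seeded replicate hierarchically and reports, per dynamic
    parameter, the deviation of the median log10 estimate from the truth
    in units of the Monte-Carlo spread (std over seeds, floored at 1e-3
    decades to avoid 0/0 in the noise-free direction), plus the median
    over seeds of the worst relative scaling error.
    """
    est_log10 = []
    scale_err = []
    truth_ref = None
    for k in range(n_seeds):
        spec = SyntheticProblemSpec(topology="cascade3",
                                    grouping="per_observable",
                                    noise_level=0.1, n_times=20,
                                    seed=seed + 1000 + k)
        problem, truth = generate_problem(spec)
        truth_ref = truth
        run = multistart_optimize(problem, "hierarchical", n_starts=n_starts,
                                  seed=seed + 2000 + k)
        est_log10.append(np.log10(run.best.theta))
        scale_err.append(
            float(np.max(np.abs(run.best.scalings / truth.scalings - 1.0)))
        )
    est_log10 = np.asarray(est_log10)
    spread = np.maximum(est_log10.std(axis=0, ddof=1), 1e-3)
    z = np.abs(np.median(est_log10, axis=0) - np.log10(truth_ref.theta)) \
        / spread
    return {
        "max_z": float(np.max(z)),
        "z_per_parameter": z.tolist(),
        "median_scaling_err": float(np.median(scale_err)),
        "scaling_err_per_seed": scale_err,
        "n_seeds": n_seeds,
        "n_starts": n_starts,
    }
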
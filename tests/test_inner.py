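"""Inner subproblem: closed forms, kink-search, coupled coordinate descent.

Oracles are independent of the implementation path: dense grid searches
(with local refinement) over (s, sigma), a sorting-free weighted-median
construction for the Laplace scaling, and direct objective comparisons.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize as sciopt

from relfit.inner import (
    DegenerateGroupError,
    gaussian_inner,
    laplace_inner_noise,
    laplace_inner_scaling,
    log10_gaussian_inner,
    observables_per_record,
    solve_inner,
)
from relfit.models import get_builtin_model
from relfit.problem import ParameterGroup, ParameterStructure, build_problem
from relfit.synthetic import SyntheticProblemSpec, generate_problem

from conftest import make_measurements

# ---------------------------------------------------------------------------
# objective restricted to one group (the oracle's own tiny implementation)
# ---------------------------------------------------------------------------


def group_objective(h, y, s, sigma, dist="gaussian", scale="linear"):
    h, y = np.asarray(h, float), np.asarray(y, float)
    sigma = max(sigma, 1e-12)
    if dist == "laplace":
        return np.sum(np.log(2 * sigma) + np.abs(y - s * h) / sigma)
    if scale == "log10":
        r = np.log10(y) - np.log10(s * h)
    else:
        r = y - s * h
    return np.sum(0.5 * np.log(2 * np.pi * sigma**2) + r**2 / (2 * sigma**2))


def grid_refine_optimum(h, y, dist="gaussian", scale="linear"):
    """Dense grid over (s, sigma) followed by Nelder-Mead refinement."""
    h, y = np.asarray(h, float), np.asarray(y, float)
    ratios = y[h != 0] / h[h != 0]
    s_lo, s_hi = np.min(ratios) - 1.0, np.max(ratios) + 1.0
    best = (np.inf, None)
    for s in np.linspace(s_lo, s_hi, 120):
        for sig in np.geomspace(1e-4, 10.0, 120):
            J = group_objective(h, y, s, sig, dist, scale)
            if J < best[0]:
                best = (J, (s, sig))
    res = sciopt.minimize(
        lambda p: group_objective(h, y, p[0], abs(p[1]), dist, scale),
        np.array(best[1]), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    return min(best[0], res.fun)


def weighted_median(values, weights):
    """Sorting-free |h|-weighted median oracle: minimizes sum w|v - m| by
    scanning candidate kinks directly."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    best = (np.inf, None)
    for m in values:
        loss = np.sum(weights * np.abs(values - m))
        if loss < best[0] - 1e-15:
            best = (loss, m)
    return best[1]


# ---------------------------------------------------------------------------
# closed-form examples (expected values confirmed by the oracles)
# ---------------------------------------------------------------------------


class TestGaussianInner:
    @pytest.mark.parametrize("h, y, s_exp, sig2_exp", [
        ([1, 2, 3], [2, 4, 6], 2.0, 0.0),      # noise-free proportional data
        ([1, 2], [1, 3], 1.4, 0.1),            # confirmed by grid oracle below
        ([2], [5], 2.5, 0.0),                  # single record interpolates
    ])
    def test_closed_form(self, h, y, s_exp, sig2_exp):
        s_hat, sig2 = gaussian_inner(np.array(h, float), np.array(y, float))
        assert s_hat == pytest.approx(s_exp, abs=1e-12)
        assert sig2 == pytest.approx(sig2_exp, abs=1e-12)

    def test_matches_grid_oracle(self):
        h, y = np.array([1.0, 2.0]), np.array([1.0, 3.0])
        s_hat, sig2 = gaussian_inner(h, y)
        J_analytic = group_objective(h, y, s_hat, np.sqrt(sig2))
        assert J_analytic <= grid_refine_optimum(h, y) + 1e-8

    def test_degenerate_group(self):
        with pytest.raises(DegenerateGroupError):
            gaussian_inner(np.zeros(3), np.ones(3))


class TestLaplaceInner:
    @pytest.mark.parametrize("h, y, s_exp", [
        ([1, 1, 1], [1, 2, 4], 2.0),
        ([1, 3], [2, 3], 1.0),  # derivative -4 below s=1, +2 on (1, 2)
    ])
    def test_kink_search(self, h, y, s_exp):
        assert laplace_inner_scaling(np.array(h, float), np.array(y, float)) \
            == pytest.approx(s_exp)

    def test_proportional_data_all_jumps_coincide(self):
        h = np.array([0.5, 1.5, 2.5])
        assert laplace_inner_scaling(h, 3.0 * h) == pytest.approx(3.0)

    @pytest.mark.parametrize("h, y, s_hat, sig_exp", [
        ([1, 1, 1], [1, 2, 4], 2.0, 1.0),
        ([1, 3], [2, 3], 1.0, 0.5),
    ])
    def test_noise_closed_form(self, h, y, s_hat, sig_exp):
        assert laplace_inner_noise(np.array(h, float), np.array(y, float),
                                   s_hat) == pytest.approx(sig_exp)

    def test_noise_free_group_gives_zero_sigma(self):
        h = np.array([1.0, 2.0])
        assert laplace_inner_noise(h, 2.0 * h, 2.0) == 0.0

    def test_equals_weighted_median(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = rng.integers(1, 12)
            h = rng.normal(0, 1, n)
            h[np.abs(h) < 1e-3] = 1.0
            y = rng.normal(0, 2, n)
            s_hat = laplace_inner_scaling(h, y)
            m = weighted_median(y / h, np.abs(h))
            # both must reach the same optimal objective (flat segments may
            # admit several minimizers)
            loss = lambda s: np.sum(np.abs(h) * np.abs(y / h - s))
            assert loss(s_hat) == pytest.approx(loss(m), rel=1e-12, abs=1e-12)

    def test_h_zero_records_excluded_from_jumps(self):
        h = np.array([0.0, 1.0, 1.0])
        y = np.array([5.0, 1.0, 3.0])
        s_hat = laplace_inner_scaling(h, y)
        assert s_hat in (1.0, 3.0)
        # and the sigma formula still counts the h=0 record via |ybar|
        assert laplace_inner_noise(h, y, s_hat) == pytest.approx(
            np.mean([5.0, abs(1 - s_hat), abs(3 - s_hat)])
        )

    def test_degenerate_group(self):
        with pytest.raises(DegenerateGroupError):
            laplace_inner_scaling(np.zeros(2), np.ones(2))


class TestLog10GaussianInner:
    def test_closed_form_example(self):
        s_hat, sig2 = log10_gaussian_inner(np.array([1.0, 1.0]),
                                           np.array([10.0, 100.0]))
        assert np.log10(s_hat) == pytest.approx(1.5)
        assert sig2 == pytest.approx(0.25)

    def test_exact_proportionality(self):
        h = np.array([0.5, 2.0, 4.0])
        s_hat, sig2 = log10_gaussian_inner(h, 3.0 * h)
        assert s_hat == pytest.approx(3.0, rel=1e-12)
        assert sig2 == pytest.approx(0.0, abs=1e-24)

    def test_log_shift_equivariance(self):
        h = np.array([1.0, 2.0])
        y = np.array([3.0, 5.0])
        s1, v1 = log10_gaussian_inner(h, y)
        s2, v2 = log10_gaussian_inner(h, 10.0 * y)
        assert s2 == pytest.approx(10.0 * s1, rel=1e-12)
        assert v2 == pytest.approx(v1, abs=1e-15)

    def test_matches_grid_oracle(self):
        h = np.array([1.0, 1.0])
        y = np.array([10.0, 100.0])
        s_hat, sig2 = log10_gaussian_inner(h, y)
        J = group_objective(h, y, s_hat, np.sqrt(sig2), scale="log10")
        assert J <= grid_refine_optimum(h, y, scale="log10") + 1e-8

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            log10_gaussian_inner(np.array([-1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# dispatching over whole problems
# ---------------------------------------------------------------------------


def test_uncoupled_dispatch_matches_per_group(conversion_problem):
    problem, truth = conversion_problem
    from relfit.simulate import simulate

    sim = simulate(problem.ode_model, problem.observation_model, truth.theta,
                   problem.unique_times)
    h = observables_per_record(problem, sim)
    sol = solve_inner(problem, h)
    assert sol.method_used == "gaussian_analytic"
    for g in range(2):
        recs = problem.records_in_scaling_group(g)
        s_hat, sig2 = gaussian_inner(h[recs], problem.y[recs])
        assert sol.scalings[g] == pytest.approx(s_hat, rel=1e-12)
        assert sol.noises[g] == pytest.approx(np.sqrt(sig2), rel=1e-12)


def test_laplace_uncoupled_dispatch():
    spec = SyntheticProblemSpec(topology="conversion_reaction",
                                noise_distribution="laplace", n_times=8,
                                seed=3)
    problem, truth = generate_problem(spec)
    from relfit.simulate import simulate

    sim = simulate(problem.ode_model, problem.observation_model, truth.theta,
                   problem.unique_times)
    h = observables_per_record(problem, sim)
    sol = solve_inner(problem, h)
    assert sol.method_used == "laplace_kinksearch"
    assert sol.jump_points is not None
    assert np.all(np.diff(sol.jump_points) >= 0)
    for g in range(2):
        recs = problem.records_in_scaling_group(g)
        assert sol.scalings[g] == pytest.approx(
            laplace_inner_scaling(h[recs], problem.y[recs]), rel=1e-12)
        assert sol.noises[g] == pytest.approx(
            laplace_inner_noise(h[recs], problem.y[recs], sol.scalings[g]),
            rel=1e-12)


def _shared_scaling_problem(seed=5, dist="gaussian"):
    """One scaling shared across both observables, each keeping its own
    noise parameter: a genuinely coupled inner problem."""
    ode, obs = get_builtin_model("conversion_reaction")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.5, 8.0, 6)
    from relfit.simulate import simulate as sim_fn

    sim = sim_fn(ode, obs, np.array([0.8, 0.2]), times)
    rows = []
    for i, name in enumerate(["A_obs", "B_obs"]):
        for k, t in enumerate(times):
            y = 2.0 * sim.observables[k, i] + rng.normal(0, 0.05 * (i + 1))
            rows.append((name, float(t), float(y)))
    df = make_measurements(rows)
    structure = ParameterStructure(
        [ParameterGroup("s_shared", "scaling", match={})],
        [ParameterGroup("sigma_A", "noise", match={"observable": "A_obs"}),
         ParameterGroup("sigma_B", "noise", match={"observable": "B_obs"})],
    )
    problem = build_problem(ode, obs, df, structure, dist)
    h = sim.observables[problem.time_idx, problem.obs_idx]
    return problem, h


@pytest.mark.parametrize("dist", ["gaussian", "laplace"])
def test_coupled_solution_beats_dense_grid(dist):
    """Coordinate descent on the shared-scaling instance reaches an
    objective at least as good as any point of a 50^3 grid over
    (s, sigma_A, sigma_B)."""
    problem, h = _shared_scaling_problem(dist=dist)
    sol = solve_inner(problem, h)
    assert sol.method_used == "coordinate_descent"
    assert sol.iterations >= 1

    def full_objective(s, sig_a, sig_b):
        J = 0.0
        for g, sig in ((0, sig_a), (1, sig_b)):
            recs = np.nonzero(problem.noise_gidx == g)[0]
            J += group_objective(h[recs], problem.y[recs], s, sig, dist)
        return J

    J_cd = full_objective(sol.scalings[0], sol.noises[0], sol.noises[1])
    grid_s = np.linspace(1.0, 3.0, 50)
    grid_sig = np.geomspace(1e-3, 1.0, 50)
    J_grid = min(
        full_objective(s, sa, sb)
        for s in grid_s for sa in grid_sig for sb in grid_sig
    )
    assert J_cd <= J_grid + 1e-9


def test_coupled_gaussian_stationarity():
    """At the coordinate-descent optimum the (s, sigma) gradient vanishes."""
    problem, h = _shared_scaling_problem()
    sol = solve_inner(problem, h)
    from relfit.util import central_difference_gradient

    def J_of(p):
        Jtot = 0.0
        for g, sig in ((0, p[1]), (1, p[2])):
            recs = np.nonzero(problem.noise_gidx == g)[0]
            Jtot += group_objective(h[recs], problem.y[recs], p[0], sig)
        return Jtot

    # coordinate descent stops on objective decrease < 1e-10, which leaves
    # a parameter error of order 1e-5 in the strongly curved s direction
    p_opt = np.array([sol.scalings[0], sol.noises[0], sol.noises[1]])
    grad = central_difference_gradient(J_of, p_opt, rel_step=1e-7)
    assert np.max(np.abs(grad)) < 1e-3


def test_fixed_groups_passed_through(conversion_problem):
    problem, truth = conversion_problem
    from dataclasses import replace

    from relfit.problem import fix_scaling_group

    structure = fix_scaling_group(problem.structure, "s_A_obs", 1.0)
    fixed_problem = build_problem(
        problem.ode_model, problem.observation_model, problem.measurements,
        structure, problem.noise_distribution,
    )
    from relfit.simulate import simulate

    sim = simulate(problem.ode_model, problem.observation_model, truth.theta,
                   problem.unique_times)
    h = observables_per_record(fixed_problem, sim)
    sol = solve_inner(fixed_problem, h)
    assert sol.scalings[0] == 1.0
    recs = fixed_problem.records_in_scaling_group(0)
    expected_sigma = np.sqrt(np.mean((fixed_problem.y[recs] - h[recs]) ** 2))
    assert sol.noises[0] == pytest.approx(expected_sigma, rel=1e-12)


def test_solve_inner_never_simulates(conversion_problem, monkeypatch):
    """The inner subproblem must not integrate the ODE."""
    problem, truth = conversion_problem
    from relfit.simulate import simulate

    sim = simulate(problem.ode_model, problem.observation_model, truth.theta,
                   problem.unique_times)
    h = observables_per_record(problem, sim)

    calls = {"n": 0}

    def counting_simulate(*args, **kwargs):
        calls["n"] += 1
        raise AssertionError("solve_inner must not simulate")

    import sys

    sim_mod = sys.modules["relfit.simulate"]
    monkeypatch.setattr(sim_mod, "solve_ivp", counting_simulate)
    sol = solve_inner(problem, h)
    assert calls["n"] == 0
    assert np.all(np.isfinite(sol.scalings))


# ---------------------------------------------------------------------------
# randomized optimality / equivariance properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("dist, scale", [
    ("gaussian", "linear"), ("laplace", "linear"), ("gaussian", "log10"),
])
def test_optimality_against_random_draws(dist, scale):
    """Closed forms beat 1000 random admissible (s, sigma) draws on random
    instances of each configuration."""
    rng = np.random.default_rng(41)
    for _ in range(30):
        n = rng.integers(1, 20)
        if scale == "log10":
            h = rng.lognormal(0, 1, n)
            y = rng.lognormal(0.5, 1, n)
        else:
            h = rng.normal(1, 1, n)
            h[h == 0] = 1.0
            y = rng.normal(1, 2, n)
        if dist == "laplace":
            s_hat = laplace_inner_scaling(h, y)
            sig_hat = laplace_inner_noise(h, y, s_hat)
        elif scale == "log10":
            s_hat, sig2 = log10_gaussian_inner(h, y)
            sig_hat = np.sqrt(sig2)
        else:
            s_hat, sig2 = gaussian_inner(h, y)
            sig_hat = np.sqrt(sig2)
        J_opt = group_objective(h, y, s_hat, sig_hat, dist, scale)
        s_draw = rng.normal(s_hat, 2.0, 1000)
        if scale == "log10":
            s_draw = np.abs(s_draw) + 1e-6
        sig_draw = rng.lognormal(np.log(max(sig_hat, 1e-3)), 1.0, 1000)
        J_draw = np.array([
            group_objective(h, y, s, sig, dist, scale)
            for s, sig in zip(s_draw, sig_draw)
        ])
        assert J_opt <= np.min(J_draw) + 1e-9


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),  # h
            st.floats(-10, 10),  # y
        ),
        min_size=1,
        max_size=15,
    ),
)
def test_kink_search_minimizes_weighted_absolute_loss(data):
    """For arbitrary groups, the kink-search result minimizes
    sum |h| |y/h - s| over a fine candidate sweep."""
    h = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    s_hat = laplace_inner_scaling(h, y)

    def loss(s):
        return np.sum(np.abs(h) * np.abs(y / h - s))

    candidates = np.concatenate([y / h, np.linspace(-3, 3, 101)])
    assert loss(s_hat) <= np.min([loss(c) for c in candidates]) + 1e-9


def test_equivariance_properties():
    """y -> c y rescales s-hat and sigma-hat; h -> c h rescales s-hat only."""
    rng = np.random.default_rng(43)
    h = rng.uniform(0.5, 2.0, 12)
    y = 1.8 * h + rng.normal(0, 0.2, 12)
    c = 2.5

    s1, v1 = gaussian_inner(h, y)
    s2, v2 = gaussian_inner(h, c * y)
    assert s2 == pytest.approx(c * s1, rel=1e-12)
    assert v2 == pytest.approx(c**2 * v1, rel=1e-10)
    s3, v3 = gaussian_inner(c * h, y)
    assert s3 == pytest.approx(s1 / c, rel=1e-12)
    assert v3 == pytest.approx(v1, rel=1e-10)

    sl1 = laplace_inner_scaling(h, y)
    sig_l1 = laplace_inner_noise(h, y, sl1)
    sl2 = laplace_inner_scaling(h, c * y)
    sig_l2 = laplace_inner_noise(h, c * y, sl2)
    assert sl2 == pytest.approx(c * sl1, rel=1e-12)
    assert sig_l2 == pytest.approx(c * sig_l1, rel=1e-12)
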
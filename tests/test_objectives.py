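"""Objective values, gradients and distributional identities.

The finite-difference oracle for every gradient check is the package's own
central-difference helper applied to the *value* path only, so gradient and
value computations are validated against each other.
"""

import numpy as np
import pytest

from relfit.objectives import (
    gaussian_nll,
    laplace_nll,
    log10_gaussian_nll,
    negative_log_likelihood,
)
from relfit.synthetic import SyntheticProblemSpec, generate_problem
from relfit.util import central_difference_gradient

from conftest import single_observable_problem

TIGHT = dict(atol=1e-12, rtol=1e-10)


def _exp_decay_h(problem, theta):
    return np.exp(-theta[0] * problem.rec_times)


class TestGaussian:
    def test_zero_residual_value(self):
        # one record with ybar = s*h exactly and sigma = 1
        problem = single_observable_problem([2.0 * np.exp(-1.0)], times=[1.0])
        res = gaussian_nll(problem, np.array([1.0]), np.array([2.0]),
                           np.array([1.0]), with_gradient=False, **TIGHT)
        assert res.value == pytest.approx(0.5 * np.log(2 * np.pi), rel=1e-9)

    def test_symmetric_residuals_value(self):
        # two records with residuals +r and -r at sigma = 1:
        # J = log(2 pi) + r^2
        r = 0.3
        h = np.exp(-np.array([1.0, 2.0]))
        problem = single_observable_problem(h + np.array([r, -r]),
                                            times=[1.0, 2.0])
        res = gaussian_nll(problem, np.array([1.0]), np.array([1.0]),
                           np.array([1.0]), with_gradient=False, **TIGHT)
        assert res.value == pytest.approx(np.log(2 * np.pi) + r**2, rel=1e-8)

    def test_negative_sigma_rejected(self):
        problem = single_observable_problem([0.5], times=[1.0])
        with pytest.raises(ValueError, match="non-negative"):
            gaussian_nll(problem, np.array([1.0]), np.array([1.0]),
                         np.array([-1.0]))

    def test_scale_equivariance(self):
        """(ybar, s, sigma) -> (c ybar, c s, c sigma) shifts J by n log c."""
        rng = np.random.default_rng(5)
        y = np.exp(-np.arange(1.0, 6.0)) * 2.0 + rng.normal(0, 0.05, 5)
        c = 3.7
        p1 = single_observable_problem(y)
        p2 = single_observable_problem(c * y)
        theta, s, sig = np.array([1.0]), np.array([2.0]), np.array([0.3])
        J1 = gaussian_nll(p1, theta, s, sig, with_gradient=False, **TIGHT).value
        J2 = gaussian_nll(p2, theta, c * s, c * sig, with_gradient=False,
                          **TIGHT).value
        assert J2 - J1 == pytest.approx(len(y) * np.log(c), rel=1e-9)


class TestLaplace:
    def test_zero_residual_value(self):
        problem = single_observable_problem([np.exp(-1.0)], times=[1.0])
        res = laplace_nll(problem, np.array([1.0]), np.array([1.0]),
                          np.array([1.0]), with_gradient=False, **TIGHT)
        assert res.value == pytest.approx(np.log(2.0), rel=1e-9)
        assert res.kink is False  # value path does not flag

    def test_positive_residual_value(self):
        r = 0.4
        problem = single_observable_problem([np.exp(-1.0) + r], times=[1.0])
        res = laplace_nll(problem, np.array([1.0]), np.array([1.0]),
                          np.array([1.0]), with_gradient=False, **TIGHT)
        assert res.value == pytest.approx(np.log(2.0) + r, rel=1e-8)

    def test_kink_flagged_with_subgradient(self):
        # build data exactly proportional to the *simulated* observable so
        # the residual is exactly zero at s = 2
        from relfit.simulate import simulate

        probe = single_observable_problem([1.0], times=[1.0])
        sim = simulate(probe.ode_model, probe.observation_model,
                       np.array([1.0]), probe.unique_times,
                       with_sensitivities=True, **TIGHT)
        h = sim.observables[0, 0]
        problem = single_observable_problem([2.0 * h], times=[1.0])
        res = laplace_nll(problem, np.array([1.0]), np.array([2.0]),
                          np.array([1.0]), with_gradient=True, **TIGHT)
        assert res.kink is True
        assert np.all(np.isfinite(res.gradient))

    def test_midpoint_convexity_in_s(self):
        """J is convex in s at fixed theta, sigma."""
        rng = np.random.default_rng(7)
        y = np.exp(-np.arange(1.0, 7.0)) + rng.normal(0, 0.1, 6)
        problem = single_observable_problem(y, noise="laplace")
        theta, sig = np.array([1.0]), np.array([0.5])

        def J(s):
            return laplace_nll(problem, theta, np.array([s]), sig,
                               with_gradient=False, **TIGHT).value

        for _ in range(25):
            a, b = rng.uniform(-2.0, 3.0, 2)
            assert J(0.5 * (a + b)) <= 0.5 * (J(a) + J(b)) + 1e-10


class TestLog10Gaussian:
    def test_zero_residual_value(self):
        s, sig = 2.0, 0.25
        h = np.exp(-np.array([1.0, 2.0]))
        problem = single_observable_problem(s * h, times=[1.0, 2.0],
                                            scale="log10")
        res = log10_gaussian_nll(problem, np.array([1.0]), np.array([s]),
                                 np.array([sig]), with_gradient=False, **TIGHT)
        assert res.value == pytest.approx(
            2 * 0.5 * np.log(2 * np.pi * sig**2), rel=1e-9
        )

    def test_scale_invariance(self):
        """Doubling both ybar and s leaves every log-residual unchanged."""
        rng = np.random.default_rng(9)
        y = 2.0 * np.exp(-np.arange(1.0, 5.0)) * 10 ** rng.normal(0, 0.05, 4)
        p1 = single_observable_problem(y, scale="log10")
        p2 = single_observable_problem(2 * y, scale="log10")
        theta, sig = np.array([1.0]), np.array([0.1])
        J1 = log10_gaussian_nll(p1, theta, np.array([2.0]), sig,
                                with_gradient=False, **TIGHT).value
        J2 = log10_gaussian_nll(p2, theta, np.array([4.0]), sig,
                                with_gradient=False, **TIGHT).value
        assert J1 == pytest.approx(J2, rel=1e-9)

    def test_nonpositive_observable_flagged_infinite(self):
        problem = single_observable_problem([0.5], times=[1.0], scale="log10")
        res = log10_gaussian_nll(problem, np.array([1.0]), np.array([-1.0]),
                                 np.array([0.1]), with_gradient=False, **TIGHT)
        assert np.isinf(res.value)
        assert res.status == "invalid_observable"


@pytest.mark.parametrize("objective, noise, scale", [
    (gaussian_nll, "gaussian", "linear"),
    (laplace_nll, "laplace", "linear"),
    (log10_gaussian_nll, "gaussian", "log10"),
])
def test_gradients_match_finite_differences(objective, noise, scale):
    """Full (theta, s, sigma) gradient vs central differences, away from
    Laplace kinks."""
    rng = np.random.default_rng(17)
    y = np.abs(2.0 * np.exp(-0.9 * np.arange(1.0, 9.0))
               + rng.normal(0, 0.1, 8)) + 0.05
    problem = single_observable_problem(y, noise=noise, scale=scale)
    theta0, s0, sig0 = 0.9, 2.1, 0.35

    def value(q):
        return objective(problem, q[:1], q[1:2], q[2:3],
                         with_gradient=False, **TIGHT).value

    q0 = np.array([theta0, s0, sig0])
    res = objective(problem, q0[:1], q0[1:2], q0[2:3], with_gradient=True,
                    **TIGHT)
    fd = central_difference_gradient(value, q0, rel_step=1e-6)
    np.testing.assert_allclose(res.gradient, fd, rtol=1e-4, atol=1e-6)


@pytest.mark.parametrize("noise", ["gaussian", "laplace"])
def test_exp_neg_J_equals_density_product(noise):
    """exp(-J) equals the product of per-record noise densities."""
    from scipy import stats

    rng = np.random.default_rng(23)
    y = np.exp(-np.arange(1.0, 5.0)) * 1.5 + rng.normal(0, 0.1, 4)
    problem = single_observable_problem(y, noise=noise)
    theta, s, sig = np.array([1.0]), np.array([1.5]), np.array([0.2])
    fn = gaussian_nll if noise == "gaussian" else laplace_nll
    J = fn(problem, theta, s, sig, with_gradient=False, **TIGHT).value
    h = _exp_decay_h(problem, theta)
    dist = stats.norm if noise == "gaussian" else stats.laplace
    dens = dist.pdf(y, loc=s[0] * h, scale=sig[0])
    assert np.exp(-J) == pytest.approx(np.prod(dens), rel=1e-7)


def test_solver_failure_gives_infinite_value(conversion_problem):
    problem, truth = conversion_problem
    res = negative_log_likelihood(
        problem, np.array([1e12, 1e12]), np.ones(2), np.ones(2),
        with_gradient=True,
    )
    if not np.isfinite(res.value):
        assert res.gradient is None and res.status != "ok"
    else:  # the integrator may still cope; then the value must be finite
        assert res.status == "ok"


def test_mixed_scale_dispatch(conversion_problem):
    """negative_log_likelihood honors each observable's declared scale."""
    problem, truth = conversion_problem
    problem.observation_model.scales = ["linear", "linear"]
    a = negative_log_likelihood(problem, truth.theta, truth.scalings,
                                truth.noises, with_gradient=False).value
    b = gaussian_nll(problem, truth.theta, truth.scalings,
                     truth.noises, with_gradient=False).value
    assert a == pytest.approx(b, rel=1e-12)
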
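"""Numerical integration of the ODE and its forward sensitivities.

The sensitivities S = dx/dtheta solve the variational system

    dS/dt = (df/dx) S + df/dtheta,   S(t0) = dx0/dtheta,

integrated here as one augmented system together with the states
(staggered schemes are not used).  Signaling models are routinely stiff,
so the default integrator is LSODA, which switches between non-stiff and
stiff (BDF) methods automatically.

Integrator failures are encoded in the result status rather than raised:
multi-start optimization must survive pathological parameter draws, and
callers map a failed simulation to an infinite objective value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .models import ObservationModel, OdeModel
from .util import central_difference_jacobian

__all__ = ["SimulationResult", "simulate"]

#: default integration tolerances (absolute / relative)
DEFAULT_ATOL = 1e-8
DEFAULT_RTOL = 1e-6


@dataclass
class SimulationResult:
    """States, observables and (optionally) their parameter sensitivities
    on the requested time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_t, n_x)
    observables: np.ndarray  # (n_t, n_y)
    state_sensitivities: Optional[np.ndarray] = None  # (n_t, n_x, n_p)
    observable_sensitivities: Optional[np.ndarray] = None  # (n_t, n_y, n_p)
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _fd_jac_state(ode: OdeModel, t: float, x: np.ndarray,
                  theta: np.ndarray) -> np.ndarray:
    return central_difference_jacobian(lambda z: ode.rhs(t, z, theta), x)


def _fd_jac_params(ode: OdeModel, t: float, x: np.ndarray,
                   theta: np.ndarray) -> np.ndarray:
    return central_difference_jacobian(lambda p: ode.rhs(t, x, p), theta)


def simulate(
    ode_model: OdeModel,
    observation_model: ObservationModel,
    theta: np.ndarray,
    times: np.ndarray,
    with_sensitivities: bool = False,
    atol: float = DEFAULT_ATOL,
    rtol: float = DEFAULT_RTOL,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model and evaluate observables at ``times``.

    ``times`` must be sorted ascending and not precede ``t0``.  With
    ``with_sensitivities=True`` the variational system is integrated as an
    augmented ODE and observable sensitivities are obtained by the chain
    rule ``dy/dtheta = (dh/dx) S + dh/dtheta``.
    """
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(times, dtype=float)
    ode, obs = ode_model, observation_model
    n_x, n_p, n_y = ode.n_states, ode.n_dynamic, obs.n_observables
    n_t = times.size

    if n_t and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if n_t and times[0] < ode.t0:
        raise ValueError("times must not precede t0")

    def failed() -> SimulationResult:
        nan = np.full((n_t, n_x), np.nan)
        nan_y = np.full((n_t, n_y), np.nan)
        return SimulationResult(
            times=times,
            states=nan,
            observables=nan_y,
            state_sensitivities=np.full((n_t, n_x, n_p), np.nan)
            if with_sensitivities else None,
            observable_sensitivities=np.full((n_t, n_y, n_p), np.nan)
            if with_sensitivities else None,
            status="solver_failure",
        )

    jac_x = ode.jac_state or (lambda t, x, p: _fd_jac_state(ode, t, x, p))
    jac_p = ode.jac_params or (lambda t, x, p: _fd_jac_params(ode, t, x, p))

    try:
        x0 = np.asarray(ode.initial_state(theta), dtype=float)
        if x0.shape != (n_x,):
            raise ValueError("initial_state returned wrong shape")

        if with_sensitivities:
            if ode.initial_state_jac is not None:
                s0 = np.asarray(ode.initial_state_jac(theta), dtype=float)
            else:
                s0 = central_difference_jacobian(
                    lambda p: np.asarray(ode.initial_state(p), dtype=float), theta
                )
            z0 = np.concatenate([x0, s0.reshape(-1)])

            def aug_rhs(t, z):
                x = z[:n_x]
                S = z[n_x:].reshape(n_x, n_p)
                dx = np.asarray(ode.rhs(t, x, theta), dtype=float)
                dS = jac_x(t, x, theta) @ S + jac_p(t, x, theta)
                return np.concatenate([dx, dS.reshape(-1)])

            y0, fun = z0, aug_rhs
        else:
            y0 = x0

            def fun(t, z):
                return np.asarray(ode.rhs(t, z, theta), dtype=float)

        t_end = times[-1] if n_t else ode.t0
        if t_end == ode.t0:
            sol_y = np.tile(y0[:, None], (1, n_t))
            success = True
        else:
            with np.errstate(all="ignore"):
                sol = solve_ivp(
                    fun,
                    (ode.t0, t_end),
                    y0,
                    t_eval=times,
                    method=method,
                    atol=atol,
                    rtol=rtol,
                )
            sol_y, success = sol.y, sol.success and np.all(np.isfinite(sol.y))
        if not success:
            return failed()
    except Exception:
        return failed()

    states = sol_y[:n_x].T  # (n_t, n_x)
    observables = np.empty((n_t, n_y))
    for k in range(n_t):
        observables[k] = np.asarray(obs.observe(states[k], theta), dtype=float)

    if not with_sensitivities:
        return SimulationResult(times=times, states=states, observables=observables)

    state_sens = sol_y[n_x:].T.reshape(n_t, n_x, n_p)
    obs_jac_x = obs.jac_state or (
        lambda x, p: central_difference_jacobian(lambda z: obs.observe(z, p), x)
    )
    obs_jac_p = obs.jac_params or (
        lambda x, p: central_difference_jacobian(lambda q: obs.observe(x, q), p)
    )
    obs_sens = np.empty((n_t, n_y, n_p))
    for k in range(n_t):
        obs_sens[k] = (
            np.asarray(obs_jac_x(states[k], theta), dtype=float) @ state_sens[k]
            + np.asarray(obs_jac_p(states[k], theta), dtype=float)
        )

    return SimulationResult(
        times=times,
        states=states,
        observables=observables,
        state_sensitivities=state_sens,
        observable_sensitivities=obs_sens,
    )
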
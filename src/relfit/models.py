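"""ODE and observation model containers plus a small library of built-in models.

An :class:`OdeModel` bundles the right-hand side ``f(t, x, theta)``, the
parameter-dependent initial state ``x0(theta)`` and bookkeeping metadata.
An :class:`ObservationModel` maps states to observables, ``y = h(x, theta)``,
and declares on which scale (linear or log10) each observable is compared
to data.  Analytic Jacobians are optional; when absent the simulator falls
back to central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "OdeModel",
    "ObservationModel",
    "get_builtin_model",
    "BUILTIN_MODELS",
]


@dataclass
class OdeModel:
    """Dynamical model ``dx/dt = f(t, x, theta)`` with ``x(t0) = x0(theta)``.

    Parameters named here are the *dynamic* parameters: rate constants and
    initial-condition parameters, as opposed to the measurement-process
    (scaling/noise) parameters handled elsewhere.
    """

    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    initial_state: Callable[[np.ndarray], np.ndarray]
    t0: float
    n_states: int
    n_dynamic: int
    state_names: Sequence[str]
    parameter_names: Sequence[str]
    # optional analytic derivatives: df/dx (n_x, n_x), df/dtheta (n_x, n_p),
    # dx0/dtheta (n_x, n_p)
    jac_state: Optional[Callable[[float, np.ndarray, np.ndarray], np.ndarray]] = None
    jac_params: Optional[Callable[[float, np.ndarray, np.ndarray], np.ndarray]] = None
    initial_state_jac: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.n_dynamic < 1:
            raise ValueError("a model needs at least one dynamic parameter")
        if len(self.state_names) != self.n_states:
            raise ValueError("state_names length must equal n_states")
        if len(self.parameter_names) != self.n_dynamic:
            raise ValueError("parameter_names length must equal n_dynamic")


@dataclass
class ObservationModel:
    """Observation map ``y = h(x, theta)`` with a declared scale per observable.

    ``scales[i]`` is ``"linear"`` or ``"log10"``; log10 observables are
    compared to data in log space (multiplicative noise).
    """

    observe: Callable[[np.ndarray, np.ndarray], np.ndarray]
    n_observables: int
    observable_names: Sequence[str]
    scales: Sequence[str] = field(default_factory=list)
    # optional analytic derivatives per state vector: dh/dx (n_y, n_x),
    # dh/dtheta (n_y, n_p)
    jac_state: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    jac_params: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if not self.scales:
            self.scales = ["linear"] * self.n_observables
        if len(self.scales) != self.n_observables:
            raise ValueError("a scale must be declared for every observable")
        for sc in self.scales:
            if sc not in ("linear", "log10"):
                raise ValueError(f"unknown observation scale {sc!r}")
        if len(self.observable_names) != self.n_observables:
            raise ValueError("observable_names length must equal n_observables")


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------


def _exp_decay() -> tuple[OdeModel, ObservationModel]:
    """Single-species first-order decay; closed form x(t) = exp(-k t)."""

    def rhs(t, x, theta):
        return np.array([-theta[0] * x[0]])

    def jac_state(t, x, theta):
        return np.array([[-theta[0]]])

    def jac_params(t, x, theta):
        return np.array([[-x[0]]])

    ode = OdeModel(
        rhs=rhs,
        initial_state=lambda theta: np.array([1.0]),
        t0=0.0,
        n_states=1,
        n_dynamic=1,
        state_names=["x"],
        parameter_names=["k"],
        jac_state=jac_state,
        jac_params=jac_params,
        initial_state_jac=lambda theta: np.zeros((1, 1)),
    )
    obs = ObservationModel(
        observe=lambda x, theta: np.asarray(x[..., :1]),
        n_observables=1,
        observable_names=["x_obs"],
        jac_state=lambda x, theta: np.eye(1),
        jac_params=lambda x, theta: np.zeros((1, 1)),
    )
    return ode, obs


def _conversion_reaction() -> tuple[OdeModel, ObservationModel]:
    """Reversible conversion A <-> B with rates k1 (forward), k2 (backward).

    Mass is conserved: A + B = A(0) + B(0) = 1.  Both species are observed,
    each through its own relative readout.
    """

    def rhs(t, x, theta):
        k1, k2 = theta
        flux = k1 * x[0] - k2 * x[1]
        return np.array([-flux, flux])

    def jac_state(t, x, theta):
        k1, k2 = theta
        return np.array([[-k1, k2], [k1, -k2]])

    def jac_params(t, x, theta):
        return np.array([[-x[0], x[1]], [x[0], -x[1]]])

    ode = OdeModel(
        rhs=rhs,
        initial_state=lambda theta: np.array([1.0, 0.0]),
        t0=0.0,
        n_states=2,
        n_dynamic=2,
        state_names=["A", "B"],
        parameter_names=["k1", "k2"],
        jac_state=jac_state,
        jac_params=jac_params,
        initial_state_jac=lambda theta: np.zeros((2, 2)),
    )
    obs = ObservationModel(
        observe=lambda x, theta: np.asarray(x),
        n_observables=2,
        observable_names=["A_obs", "B_obs"],
        jac_state=lambda x, theta: np.eye(2),
        jac_params=lambda x, theta: np.zeros((2, 2)),
    )
    return ode, obs


# fixed upstream activity of the cascade's top tier: relaxation from full
# activation to a maintenance level after stimulus step-down (measured in a
# separate calibration, hence known — the same device as a measured
# receptor-input spline)
_CASCADE_U_FLOOR = 0.5
_CASCADE_U_RATE = 0.6


def _cascade_input(t: float) -> float:
    return _CASCADE_U_FLOOR + (1.0 - _CASCADE_U_FLOOR) * np.exp(
        -_CASCADE_U_RATE * t
    )


def _cascade3() -> tuple[OdeModel, ObservationModel]:
    """Three-tier phosphorylation cascade relaxing after stimulus step-down.

    The top tier's activity u(t) is a known measured input profile; the two
    downstream tiers are the phosphorylated fractions of conserved pools
    (totals normalized to 1), tracked by Western blot while the system
    relaxes from full phosphorylation:

        x1' = k1 u(t) (1 - x1) - k2 x1     x(0) = (1, 1)
        x2' = k3 x1 (1 - x2) - k4 x2

    Structurally this mimics a RAF/MEK/ERK-type study (upstream activity
    known, pMEK/pERK measured on relative scale).  The known initial
    phosphorylation level anchors the absolute scale of both observed
    trajectories (y_i(0) = s_i), and the non-constant input separates the
    activation and deactivation rates, so the dynamic parameters and the
    scalings are structurally identifiable from relative data — an
    activation-from-zero design would leave an exact gain/scaling
    trade-off instead.
    """

    def rhs(t, x, theta):
        k1, k2, k3, k4 = theta
        u = _cascade_input(t)
        return np.array(
            [
                k1 * u * (1.0 - x[0]) - k2 * x[0],
                k3 * x[0] * (1.0 - x[1]) - k4 * x[1],
            ]
        )

    def jac_state(t, x, theta):
        k1, k2, k3, k4 = theta
        u = _cascade_input(t)
        return np.array(
            [
                [-k1 * u - k2, 0.0],
                [k3 * (1.0 - x[1]), -k3 * x[0] - k4],
            ]
        )

    def jac_params(t, x, theta):
        u = _cascade_input(t)
        return np.array(
            [
                [u * (1.0 - x[0]), -x[0], 0.0, 0.0],
                [0.0, 0.0, x[0] * (1.0 - x[1]), -x[1]],
            ]
        )

    ode = OdeModel(
        rhs=rhs,
        initial_state=lambda theta: np.ones(2),
        t0=0.0,
        n_states=2,
        n_dynamic=4,
        state_names=["pTier2", "pTier3"],
        parameter_names=["k1", "k2", "k3", "k4"],
        jac_state=jac_state,
        jac_params=jac_params,
        initial_state_jac=lambda theta: np.zeros((2, 4)),
    )

    obs = ObservationModel(
        observe=lambda x, theta: np.asarray(x),
        n_observables=2,
        observable_names=["pTier2_obs", "pTier3_obs"],
        jac_state=lambda x, theta: np.eye(2),
        jac_params=lambda x, theta: np.zeros((2, 4)),
    )
    return ode, obs


# fixed receptor-input rates of the spline_input_pathway (not estimated)
_INPUT_RISE = 1.0
_INPUT_DECAY = 0.1


def _pathway_input(t: float) -> float:
    """Fixed smooth receptor activity: difference of two exponentials."""
    return float(np.exp(-_INPUT_DECAY * t) - np.exp(-_INPUT_RISE * t))


def _spline_input_pathway() -> tuple[OdeModel, ObservationModel]:
    """Two-state pathway driven by a fixed transient input u(t).

    Mimics a JAK-STAT-type structure: an upstream receptor signal u(t)
    (fixed function, playing the role of the measured pEpoR spline) drives
    phosphorylation of a downstream species which is then converted further:

        x1' = k1 u(t) - k2 x1      (phosphorylated species)
        x2' = k3 x1 - k4 x2        (downstream product)

    Observables are the phospho-form x1 and the "total" x1 + x2.
    """

    def rhs(t, x, theta):
        k1, k2, k3, k4 = theta
        u = _pathway_input(t)
        return np.array([k1 * u - k2 * x[0], k3 * x[0] - k4 * x[1]])

    def jac_state(t, x, theta):
        k1, k2, k3, k4 = theta
        return np.array([[-k2, 0.0], [k3, -k4]])

    def jac_params(t, x, theta):
        u = _pathway_input(t)
        return np.array([[u, -x[0], 0.0, 0.0], [0.0, 0.0, x[0], -x[1]]])

    ode = OdeModel(
        rhs=rhs,
        initial_state=lambda theta: np.zeros(2),
        t0=0.0,
        n_states=2,
        n_dynamic=4,
        state_names=["pS", "pSd"],
        parameter_names=["k1", "k2", "k3", "k4"],
        jac_state=jac_state,
        jac_params=jac_params,
        initial_state_jac=lambda theta: np.zeros((2, 4)),
    )

    def observe(x, theta):
        x = np.asarray(x)
        return np.stack([x[..., 0], x[..., 0] + x[..., 1]], axis=-1)

    obs = ObservationModel(
        observe=observe,
        n_observables=2,
        observable_names=["pS_obs", "tS_obs"],
        jac_state=lambda x, theta: np.array([[1.0, 0.0], [1.0, 1.0]]),
        jac_params=lambda x, theta: np.zeros((2, 4)),
    )
    return ode, obs


BUILTIN_MODELS = {
    "exp_decay": _exp_decay,
    "conversion_reaction": _conversion_reaction,
    "cascade3": _cascade3,
    "spline_input_pathway": _spline_input_pathway,
}


def get_builtin_model(name: str) -> tuple[OdeModel, ObservationModel]:
    """Return a fresh ``(OdeModel, ObservationModel)`` pair for a built-in model."""
    try:
        factory = BUILTIN_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in model {name!r}; available: {sorted(BUILTIN_MODELS)}"
        ) from None
    return factory()
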
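"""Small numerical helpers shared across modules."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["central_difference_jacobian", "central_difference_gradient"]


def central_difference_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    rel_step: float = 1e-6,
    abs_step: float = 1e-8,
) -> np.ndarray:
    """Jacobian of a vector-valued function by central differences.

    Step per coordinate is ``rel_step * |x_i| + abs_step`` so that both
    large and near-zero coordinates get a sensible perturbation.
    """
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x), dtype=float)
    jac = np.empty(f0.shape + (x.size,), dtype=float)
    for i in range(x.size):
        h = rel_step * abs(x[i]) + abs_step
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        jac[..., i] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * h)
    return jac


def central_difference_gradient(
    fun: Callable[[np.ndarray], float],
    x: np.ndarray,
    rel_step: float = 1e-6,
    abs_step: float = 1e-8,
) -> np.ndarray:
    """Gradient of a scalar function by central differences."""
    return central_difference_jacobian(lambda z: np.atleast_1d(fun(z)), x,
                                       rel_step=rel_step, abs_step=abs_step)[0]
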
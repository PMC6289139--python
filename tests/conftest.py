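import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from relfit.models import get_builtin_model
from relfit.problem import (
    MEASUREMENT_COLUMNS,
    ParameterStructure,
    build_problem,
    per_observable_structure,
)
from relfit.synthetic import SyntheticProblemSpec, generate_problem


def make_measurements(rows):
    """rows: (observableId, time, measurement[, replicateId[, experimentId]])"""
    full = []
    for r in rows:
        r = list(r)
        while len(r) < 5:
            r.append("r0" if len(r) == 3 else "e0")
        full.append(r)
    return pd.DataFrame(full, columns=MEASUREMENT_COLUMNS)


@pytest.fixture
def conversion_problem():
    """Small Gaussian conversion-reaction problem with known truth."""
    spec = SyntheticProblemSpec(
        topology="conversion_reaction", n_times=10, seed=11
    )
    problem, truth = generate_problem(spec)
    return problem, truth


@pytest.fixture
def decay_components():
    return get_builtin_model("exp_decay")


def single_observable_problem(y_values, times=None, noise="gaussian",
                              scale="linear", fixed_noise=None):
    """One-observable exp-decay problem with explicit measurement values."""
    ode, obs = get_builtin_model("exp_decay")
    if scale == "log10":
        obs.scales = ["log10"]
    times = np.arange(1.0, len(y_values) + 1.0) if times is None else times
    df = make_measurements(
        [("x_obs", float(t), float(v)) for t, v in zip(times, y_values)]
    )
    structure = per_observable_structure(
        ["x_obs"], fixed_noises={"x_obs": fixed_noise} if fixed_noise else None
    )
    return build_problem(ode, obs, df, structure, noise)
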
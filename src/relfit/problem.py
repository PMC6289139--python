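"""Estimation-problem definition: data, parameter structure and validation.

A fitting problem for relative data combines four ingredients:

* an :class:`~relfit.models.OdeModel` (dynamic parameters theta),
* an :class:`~relfit.models.ObservationModel` (observables, their scales),
* a measurement table (observable id, time, value, replicate/experiment id),
* a :class:`ParameterStructure` declaring the scaling parameters ``s`` and
  noise parameters ``sigma``: which measurements share them (grouping),
  which are fixed, and their bounds/optimization scale.

Every measurement record belongs to exactly one scaling group and one noise
group.  The default grouping — one ``s_i`` and one ``sigma_i`` per
observable, shared over time points — matches the most common Western-blot
setup; groups may equally span replicates, experiments or observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ObservationModel, OdeModel

__all__ = [
    "ParameterGroup",
    "ParameterStructure",
    "EstimationProblem",
    "build_problem",
    "count_parameters",
    "per_observable_structure",
    "build_case_study_structure",
    "case_study_problem",
    "MEASUREMENT_COLUMNS",
]

#: canonical measurement-table columns (PEtab-flavored)
MEASUREMENT_COLUMNS = [
    "observableId",
    "time",
    "measurement",
    "replicateId",
    "experimentId",
]

#: default bounds for free parameters, on log10 scale
DEFAULT_BOUNDS = (1e-5, 1e5)


@dataclass
class ParameterGroup:
    """One scaling or noise parameter and the measurements that share it.

    ``match`` maps record fields (``observable``, ``replicate``,
    ``experiment``) to required values; ``"*"`` (or an absent key) matches
    anything.  A fixed group carries ``fixed_value`` and is excluded from
    the free-parameter count.
    """

    group_id: str
    kind: str  # "scaling" | "noise"
    match: Mapping[str, str] = field(default_factory=dict)
    fixed_value: Optional[float] = None
    lb: float = DEFAULT_BOUNDS[0]
    ub: float = DEFAULT_BOUNDS[1]
    scale: str = "log10"

    def __post_init__(self) -> None:
        if self.kind not in ("scaling", "noise"):
            raise ValueError(f"group kind must be scaling|noise, got {self.kind!r}")
        if self.scale not in ("lin", "log10"):
            raise ValueError(f"parameter scale must be lin|log10, got {self.scale!r}")
        if not self.lb < self.ub:
            raise ValueError(f"group {self.group_id}: lower bound must be < upper bound")

    @property
    def is_fixed(self) -> bool:
        return self.fixed_value is not None

    def matches(self, observable: str, replicate: str, experiment: str) -> bool:
        values = {"observable": observable, "replicate": replicate,
                  "experiment": experiment}
        for key, want in self.match.items():
            if want != "*" and values.get(key) != want:
                return False
        return True


@dataclass
class ParameterStructure:
    """Grouping, fixing and bounds of scaling/noise parameters, plus the
    bounds/scales of the dynamic parameters."""

    scaling_groups: Sequence[ParameterGroup]
    noise_groups: Sequence[ParameterGroup]
    dynamic_bounds: Optional[np.ndarray] = None  # (n_dynamic, 2)
    dynamic_scales: Optional[Sequence[str]] = None

    @property
    def n_scaling(self) -> int:
        """Number of free scaling parameters (fixed groups excluded)."""
        return sum(not g.is_fixed for g in self.scaling_groups)

    @property
    def n_noise(self) -> int:
        return sum(not g.is_fixed for g in self.noise_groups)

    def resolve_dynamic(self, n_dynamic: int) -> tuple[np.ndarray, list[str]]:
        """Bounds/scales for the dynamic block, filling defaults."""
        if self.dynamic_bounds is None:
            bounds = np.tile(np.array(DEFAULT_BOUNDS), (n_dynamic, 1))
        else:
            bounds = np.asarray(self.dynamic_bounds, dtype=float)
            if bounds.shape != (n_dynamic, 2):
                raise ValueError("dynamic_bounds shape must be (n_dynamic, 2)")
        if self.dynamic_scales is None:
            scales = ["log10"] * n_dynamic
        else:
            scales = list(self.dynamic_scales)
            if len(scales) != n_dynamic:
                raise ValueError("dynamic_scales length must equal n_dynamic")
        if np.any(bounds[:, 0] >= bounds[:, 1]):
            raise ValueError("dynamic lower bounds must be < upper bounds")
        return bounds, scales


class ProblemValidationError(ValueError):
    """Raised when problem components are inconsistent."""


@dataclass
class EstimationProblem:
    """Validated estimation problem with cross-indexed records.

    The full parameter vector of the standard (joint) formulation is
    ``q = (theta, s_free, sigma_free)``; the hierarchical outer problem
    optimizes only ``theta``.
    """

    ode_model: OdeModel
    observation_model: ObservationModel
    measurements: pd.DataFrame
    structure: ParameterStructure
    noise_distribution: str = "gaussian"

    # filled by build_problem -------------------------------------------------
    obs_idx: np.ndarray = field(default=None, repr=False)
    rec_times: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)
    scaling_gidx: np.ndarray = field(default=None, repr=False)
    noise_gidx: np.ndarray = field(default=None, repr=False)
    unique_times: np.ndarray = field(default=None, repr=False)
    time_idx: np.ndarray = field(default=None, repr=False)
    record_scale_log10: np.ndarray = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.measurements)

    @property
    def n_dynamic(self) -> int:
        return self.ode_model.n_dynamic

    def records_in_scaling_group(self, gidx: int) -> np.ndarray:
        return np.nonzero(self.scaling_gidx == gidx)[0]

    def records_in_noise_group(self, gidx: int) -> np.ndarray:
        return np.nonzero(self.noise_gidx == gidx)[0]


def _assign_groups(df: pd.DataFrame, groups: Sequence[ParameterGroup],
                   kind: str) -> np.ndarray:
    idx = np.full(len(df), -1, dtype=int)
    for r, row in enumerate(df.itertuples(index=False)):
        hits = [
            g for g, grp in enumerate(groups)
            if grp.matches(row.observableId, str(row.replicateId),
                           str(row.experimentId))
        ]
        if len(hits) == 0:
            raise ProblemValidationError(
                f"record {r} ({row.observableId}, t={row.time}) matches no "
                f"{kind} group"
            )
        if len(hits) > 1:
            ids = [groups[g].group_id for g in hits]
            raise ProblemValidationError(
                f"record {r} ({row.observableId}, t={row.time}) matches "
                f"multiple {kind} groups: {ids}"
            )
        idx[r] = hits[0]
    for g, grp in enumerate(groups):
        if not np.any(idx == g):
            raise ProblemValidationError(
                f"empty {kind} group {grp.group_id!r}: no measurement belongs to it"
            )
    return idx


def build_problem(
    ode_model: OdeModel,
    observation_model: ObservationModel,
    measurements: pd.DataFrame,
    structure: ParameterStructure,
    noise_distribution: str = "gaussian",
) -> EstimationProblem:
    """Validate components and cross-index measurements by group.

    Raises :class:`ProblemValidationError` on unknown observables,
    non-finite measurements, non-positive measurements of log10-scale
    observables, ambiguous or empty groups, or inconsistent bounds.
    """
    if noise_distribution not in ("gaussian", "laplace"):
        raise ProblemValidationError(
            f"noise_distribution must be gaussian|laplace, got {noise_distribution!r}"
        )
    df = measurements.copy()
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ProblemValidationError(f"measurement table misses columns {missing}")
    df["replicateId"] = df["replicateId"].astype(str)
    df["experimentId"] = df["experimentId"].astype(str)
    df = df.reset_index(drop=True)

    names = list(observation_model.observable_names)
    unknown = sorted(set(df["observableId"]) - set(names))
    if unknown:
        raise ProblemValidationError(f"records reference unknown observables {unknown}")

    values = df["measurement"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ProblemValidationError("non-finite measurement values present")

    obs_idx = np.array([names.index(o) for o in df["observableId"]], dtype=int)
    scales = np.array(observation_model.scales)
    record_log10 = scales[obs_idx] == "log10"
    if np.any(record_log10 & (values <= 0)):
        raise ProblemValidationError(
            "log10-scale observables require strictly positive measurements"
        )

    times = df["time"].to_numpy(dtype=float)
    if np.any(times < ode_model.t0):
        raise ProblemValidationError("measurement times before t0")

    scaling_gidx = _assign_groups(df, structure.scaling_groups, "scaling")
    noise_gidx = _assign_groups(df, structure.noise_groups, "noise")

    # groups must be homogeneous in observation scale (the analytic inner
    # solutions are scale-specific)
    for kind, groups, gidx in (
        ("scaling", structure.scaling_groups, scaling_gidx),
        ("noise", structure.noise_groups, noise_gidx),
    ):
        for g, grp in enumerate(groups):
            in_g = record_log10[gidx == g]
            if in_g.size and not (in_g.all() or not in_g.any()):
                raise ProblemValidationError(
                    f"{kind} group {grp.group_id!r} mixes linear and log10 observables"
                )

    structure.resolve_dynamic(ode_model.n_dynamic)  # validates bounds

    unique_times, time_idx = np.unique(times, return_inverse=True)

    return EstimationProblem(
        ode_model=ode_model,
        observation_model=observation_model,
        measurements=df,
        structure=structure,
        noise_distribution=noise_distribution,
        obs_idx=obs_idx,
        rec_times=times,
        y=values,
        scaling_gidx=scaling_gidx,
        noise_gidx=noise_gidx,
        unique_times=unique_times,
        time_idx=time_idx,
        record_scale_log10=record_log10,
    )


def count_parameters(problem: EstimationProblem) -> tuple[int, int, int]:
    """Return ``(n_total, n_outer, n_inner)``.

    ``n_outer`` is the dimension of the hierarchical outer subproblem
    (the dynamic parameters); ``n_inner`` counts the free scaling and noise
    parameters eliminated by the inner subproblem; the standard joint
    formulation has dimension ``n_total = n_outer + n_inner``.
    """
    n_outer = problem.ode_model.n_dynamic
    n_inner = problem.structure.n_scaling + problem.structure.n_noise
    return n_outer + n_inner, n_outer, n_inner


def per_observable_structure(
    observable_names: Sequence[str],
    fixed_scalings: Optional[Mapping[str, float]] = None,
    fixed_noises: Optional[Mapping[str, float]] = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    noise_bounds: Optional[tuple[float, float]] = None,
    scale: str = "log10",
    dynamic_bounds: Optional[np.ndarray] = None,
) -> ParameterStructure:
    """Default structure: one scaling and one noise parameter per observable,
    shared across time points, replicates and experiments."""
    fixed_scalings = fixed_scalings or {}
    fixed_noises = fixed_noises or {}
    noise_bounds = noise_bounds or bounds
    scaling = [
        ParameterGroup(
            group_id=f"s_{name}",
            kind="scaling",
            match={"observable": name},
            fixed_value=fixed_scalings.get(name),
            lb=bounds[0],
            ub=bounds[1],
            scale=scale,
        )
        for name in observable_names
    ]
    noise = [
        ParameterGroup(
            group_id=f"sigma_{name}",
            kind="noise",
            match={"observable": name},
            fixed_value=fixed_noises.get(name),
            lb=noise_bounds[0],
            ub=noise_bounds[1],
            scale=scale,
        )
        for name in observable_names
    ]
    return ParameterStructure(scaling, noise, dynamic_bounds=dynamic_bounds)


# ---------------------------------------------------------------------------
# Case-study parameter-structure fixtures (published signaling pathways)
# ---------------------------------------------------------------------------
#
# Only the parameter-structure skeletons are represented — the grouping and
# the published parameter counts.  No experimental data and no pathway ODEs
# are stored; the measurement grids built by `case_study_problem` are
# synthetic placeholders for structural bookkeeping only.

_CASE_STUDIES = ("jakstat1", "jakstat2", "rafmekerk")


def build_case_study_structure(name: str) -> tuple[ParameterStructure, int]:
    """Parameter-structure skeleton of a published case study.

    Returns ``(structure, n_dynamic)``:

    * ``jakstat1`` — Epo-induced JAK-STAT signaling: 11 dynamic parameters;
      per-observable scalings for pSTAT5 and tSTAT5, the pEpoR scaling fixed
      to 1 to remove a structural non-identifiability; one noise parameter
      per observable (16 parameters in total).
    * ``jakstat2`` — extended JAK-STAT model with CIS/SOCS3 gene expression:
      43 scaling and 11 noise parameters on top of 58 dynamic parameters
      (112 in total).  Only the cardinalities are represented; the detailed
      sharing pattern across its many experiments is not reproduced.
    * ``rafmekerk`` — RAF/MEK/ERK cascade: pMEK and pERK blots with four
      replicates, each observable/replicate pair owning its scaling and
      noise parameter (16 measurement parameters, 28 in total).
    """
    if name == "jakstat1":
        observables = ["pEpoR", "pSTAT5", "tSTAT5"]
        structure = per_observable_structure(
            observables, fixed_scalings={"pEpoR": 1.0}
        )
        return structure, 11
    if name == "jakstat2":
        scaling = [
            ParameterGroup(f"s_{i:02d}", "scaling", match={"observable": f"y{i:02d}"})
            for i in range(43)
        ]
        noise = [
            ParameterGroup(
                f"sigma_{j:02d}",
                "noise",
                match={"experiment": f"e{j:02d}"},
            )
            for j in range(11)
        ]
        return ParameterStructure(scaling, noise), 58
    if name == "rafmekerk":
        scaling = []
        noise = []
        for obs in ("pMEK", "pERK"):
            for rep in range(4):
                match = {"observable": obs, "replicate": f"r{rep}"}
                scaling.append(
                    ParameterGroup(f"s_{obs}_r{rep}", "scaling", match=match)
                )
                noise.append(
                    ParameterGroup(f"sigma_{obs}_r{rep}", "noise", match=match)
                )
        return ParameterStructure(scaling, noise), 12
    raise KeyError(f"unknown case study {name!r}; available: {_CASE_STUDIES}")


def _placeholder_model(n_states: int, n_dynamic: int,
                       observables: Sequence[str]) -> tuple[OdeModel, ObservationModel]:
    """Inert stand-in model used only for parameter-count bookkeeping
    (synthetic; carries no pathway biology)."""
    ode = OdeModel(
        rhs=lambda t, x, theta: np.zeros(n_states),
        initial_state=lambda theta: np.ones(n_states),
        t0=0.0,
        n_states=n_states,
        n_dynamic=n_dynamic,
        state_names=[f"x{i}" for i in range(n_states)],
        parameter_names=[f"theta{i}" for i in range(n_dynamic)],
    )
    n_y = len(observables)
    obs = ObservationModel(
        observe=lambda x, theta: np.ones(np.shape(x)[:-1] + (n_y,)),
        n_observables=n_y,
        observable_names=list(observables),
    )
    return ode, obs


def case_study_problem(name: str) -> EstimationProblem:
    """Full :class:`EstimationProblem` for a case-study skeleton, with a
    synthetic placeholder measurement grid (value 1.0 everywhere).

    Intended only for parameter-count bookkeeping, e.g. with
    :func:`count_parameters`; nothing here reproduces published data.
    """
    structure, n_dynamic = build_case_study_structure(name)
    rows = []
    if name == "jakstat1":
        # 46 data points at 16 time points: full grids for pEpoR/pSTAT5,
        # tSTAT5 missing the two earliest points (synthetic breakdown)
        times = np.linspace(0.0, 60.0, 16)
        for obs in ("pEpoR", "pSTAT5"):
            rows += [(obs, t, 1.0, "r0", "e0") for t in times]
        rows += [("tSTAT5", t, 1.0, "r0", "e0") for t in times[2:]]
        observables = ["pEpoR", "pSTAT5", "tSTAT5"]
    elif name == "jakstat2":
        # cardinality placeholder: one record per scaling group, experiments
        # cycling through the 11 noise groups
        for i in range(43):
            rows.append((f"y{i:02d}", float(i), 1.0, "r0", f"e{i % 11:02d}"))
        observables = [f"y{i:02d}" for i in range(43)]
    elif name == "rafmekerk":
        times = np.linspace(0.0, 60.0, 7)
        for obs in ("pMEK", "pERK"):
            for rep in range(4):
                rows += [(obs, t, 1.0, f"r{rep}", "e0") for t in times]
        observables = ["pMEK", "pERK"]
    else:
        raise KeyError(f"unknown case study {name!r}; available: {_CASE_STUDIES}")

    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    ode, obs_model = _placeholder_model(
        n_states=1, n_dynamic=n_dynamic, observables=observables
    )
    return build_problem(ode, obs_model, df, structure)


def fix_scaling_group(structure: ParameterStructure, group_id: str,
                      value: float) -> ParameterStructure:
    """Return a copy of ``structure`` with one scaling group fixed."""
    new_groups = [
        replace(g, fixed_value=value) if g.group_id == group_id else g
        for g in structure.scaling_groups
    ]
    if all(g.group_id != group_id for g in structure.scaling_groups):
        raise KeyError(f"no scaling group {group_id!r}")
    return replace(structure, scaling_groups=new_groups)
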
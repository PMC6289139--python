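"""Readers and writers: TSV tables, YAML problem bundles, JSON results.

The measurement table is PEtab-flavored TSV with columns
``observableId, time, measurement, replicateId, experimentId``.

The parameter-structure table is TSV with columns
``parameterId, type, groupKey, fixedValue, lowerBound, upperBound,
parameterScale``, where ``type`` is ``dynamic``, ``scaling`` or ``noise``
and ``groupKey`` encodes which records share a measurement parameter as
semicolon-joined ``field=value`` conditions over ``observable``,
``replicate`` and ``experiment`` (``*`` matches anything), e.g.
``observable=pMEK;replicate=r1``.

A problem bundle is a small YAML file naming a built-in (or registered)
model plugin and the two TSVs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import BUILTIN_MODELS, get_builtin_model
from .problem import (
    MEASUREMENT_COLUMNS,
    EstimationProblem,
    ParameterGroup,
    ParameterStructure,
    build_problem,
)

__all__ = [
    "write_measurements",
    "read_measurements",
    "write_parameter_table",
    "read_parameter_table",
    "write_problem_bundle",
    "read_problem_bundle",
    "save_results_json",
    "config_hash",
]

PARAMETER_COLUMNS = [
    "parameterId",
    "type",
    "groupKey",
    "fixedValue",
    "lowerBound",
    "upperBound",
    "parameterScale",
]


def write_measurements(measurements: pd.DataFrame, path) -> Path:
    path = Path(path)
    measurements[MEASUREMENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicateId": str, "experimentId": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} misses columns {missing}")
    return df


def _encode_group_key(match: dict) -> str:
    if not match:
        return "*"
    return ";".join(f"{k}={v}" for k, v in sorted(match.items()))


def _decode_group_key(key: str) -> dict:
    key = str(key).strip()
    if key in ("", "*", "nan"):
        return {}
    match = {}
    for part in key.split(";"):
        if "=" not in part:
            raise ValueError(f"malformed groupKey fragment {part!r}")
        k, v = part.split("=", 1)
        if k not in ("observable", "replicate", "experiment"):
            raise ValueError(f"unknown groupKey field {k!r}")
        match[k] = v
    return match


def write_parameter_table(path, structure: ParameterStructure,
                          parameter_names, n_dynamic: int) -> Path:
    """Serialize the parameter structure (dynamic bounds included)."""
    bounds, scales = structure.resolve_dynamic(n_dynamic)
    rows = []
    for name, (lo, hi), sc in zip(parameter_names, bounds, scales):
        rows.append((name, "dynamic", "", "", lo, hi, sc))
    for kind, groups in (("scaling", structure.scaling_groups),
                         ("noise", structure.noise_groups)):
        for g in groups:
            rows.append((
                g.group_id, kind, _encode_group_key(dict(g.match)),
                "" if g.fixed_value is None else g.fixed_value,
                g.lb, g.ub, g.scale,
            ))
    df = pd.DataFrame(rows, columns=PARAMETER_COLUMNS)
    df.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_parameter_table(path, parameter_names) -> ParameterStructure:
    df = pd.read_csv(path, sep="\t", dtype={"groupKey": str})
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table {path} misses columns {missing}")

    scaling, noise = [], []
    dyn_bounds = {}
    dyn_scales = {}
    for row in df.itertuples(index=False):
        if row.type == "dynamic":
            dyn_bounds[row.parameterId] = (float(row.lowerBound),
                                           float(row.upperBound))
            dyn_scales[row.parameterId] = str(row.parameterScale)
            continue
        if row.type not in ("scaling", "noise"):
            raise ValueError(f"unknown parameter type {row.type!r}")
        fixed = None
        if not (pd.isna(row.fixedValue) or str(row.fixedValue).strip() == ""):
            fixed = float(row.fixedValue)
        group = ParameterGroup(
            group_id=str(row.parameterId),
            kind=row.type,
            match=_decode_group_key(row.groupKey),
            fixed_value=fixed,
            lb=float(row.lowerBound),
            ub=float(row.upperBound),
            scale=str(row.parameterScale),
        )
        (scaling if row.type == "scaling" else noise).append(group)

    parameter_names = list(parameter_names)
    unknown = sorted(set(dyn_bounds) - set(parameter_names))
    if unknown:
        raise ValueError(f"dynamic rows for unknown model parameters {unknown}")
    dynamic_bounds = None
    dynamic_scales = None
    if dyn_bounds:
        if set(dyn_bounds) != set(parameter_names):
            missing_dyn = sorted(set(parameter_names) - set(dyn_bounds))
            raise ValueError(f"dynamic rows missing for parameters {missing_dyn}")
        dynamic_bounds = np.array([dyn_bounds[n] for n in parameter_names])
        dynamic_scales = [dyn_scales[n] for n in parameter_names]
    return ParameterStructure(scaling, noise, dynamic_bounds=dynamic_bounds,
                              dynamic_scales=dynamic_scales)


def write_problem_bundle(directory, problem: EstimationProblem,
                         model_name: str, stem: str = "problem") -> Path:
    """Write measurements + parameter table + YAML config into a directory;
    returns the YAML path.  ``model_name`` must name a built-in model so the
    bundle can be reloaded without code."""
    if model_name not in BUILTIN_MODELS:
        raise ValueError(f"{model_name!r} is not a built-in model")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meas = directory / f"{stem}_measurements.tsv"
    pars = directory / f"{stem}_parameters.tsv"
    write_measurements(problem.measurements, meas)
    write_parameter_table(pars, problem.structure,
                          problem.ode_model.parameter_names,
                          problem.n_dynamic)
    config = {
        "model": model_name,
        "measurements": meas.name,
        "parameters": pars.name,
        "noise_distribution": problem.noise_distribution,
    }
    out = directory / f"{stem}.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out


def read_problem_bundle(path) -> EstimationProblem:
    """Load a YAML problem bundle (paths resolved relative to the YAML)."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    for key in ("model", "measurements", "parameters"):
        if key not in config:
            raise ValueError(f"problem bundle {path} misses key {key!r}")
    ode, obs = get_builtin_model(config["model"])
    meas = read_measurements(path.parent / config["measurements"])
    structure = read_parameter_table(path.parent / config["parameters"],
                                     ode.parameter_names)
    return build_problem(ode, obs, meas, structure,
                         config.get("noise_distribution", "gaussian"))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonify(obj.item())
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def save_results_json(path, payload: dict, config: Optional[dict] = None,
                      seed: Optional[int] = None) -> Path:
    """Write a results JSON embedding tool version, config hash and seed."""
    config = config or {}
    doc = {
        "tool": "relfit",
        "version": __version__,
        "seed": seed,
        "config": _jsonify(config),
        "config_hash": config_hash(_jsonify(config)),
    }
    doc.update(_jsonify(payload))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=False)
    return path
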
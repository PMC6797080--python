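"""Hierarchical sampling from a juncture model and sample-specific truths.

A draw walks the DAG in topological order: exogenous nodes are sampled at
their own level (with correlated-error pairs drawn jointly, practitioner
values inheriting their organization's context), binary decisions are
latent-utility thresholds ``d = 1[index + ε > 0]`` with ε ~ N(0, 1),
continuous nodes are linear with normal errors, and aggregates are
computed exactly.  Every error draw is retained, which makes the dataset
replayable: true sample effects are computed by abduction–action–
prediction, re-running the structural equations under an intervention
with all errors held fixed.

Selection is encoded as missing-by-selection: variables downstream of the
implementation decision are computed internally for every unit but masked
(NaN) in the public tables wherever the organization chose not to
implement, so negative-control analyses on the full tables stay possible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_spec import Hierarchy, JunctureModel, ModelInputError

__all__ = [
    "PopulationConfig",
    "SimulatedDataset",
    "TrueEffects",
    "SimulationNumericError",
    "ReplayContractError",
    "DatasetIOError",
    "draw_population",
    "replay",
    "true_sample_effects",
    "write_dataset",
    "read_dataset",
]

_LEVEL_RANK = {"organization": 0, "practitioner": 1, "patient": 2}


class SimulationNumericError(ArithmeticError):
    """Non-finite values produced while evaluating a structural equation."""


class ReplayContractError(RuntimeError):
    """Replay requested on a dataset without retained error draws."""


class DatasetIOError(ValueError):
    """Malformed dataset bundle on disk."""


@dataclass(frozen=True)
class PopulationConfig:
    organizations: int
    practitioners_per_organization: int
    patients_per_practitioner: int
    seed: int = 0

    @classmethod
    def from_model(cls, model: JunctureModel, seed: int = 0) -> "PopulationConfig":
        h = model.hierarchy
        return cls(
            h.organizations,
            h.practitioners_per_organization,
            h.patients_per_practitioner,
            seed,
        )

    @property
    def hierarchy(self) -> Hierarchy:
        return Hierarchy(
            self.organizations,
            self.practitioners_per_organization,
            self.patients_per_practitioner,
        )


@dataclass
class SimulatedDataset:
    """One hierarchical draw: public (selection-masked) tables plus the
    complete latent values and retained errors needed for replay."""

    organizations: pd.DataFrame
    practitioners: pd.DataFrame
    patients: pd.DataFrame
    values: dict  # node -> complete ndarray at the node's level
    errors: Optional[dict]  # node -> retained error draws (None after lossy read)
    pract_org: np.ndarray  # practitioner -> organization index
    pat_pract: np.ndarray  # patient -> practitioner index
    hierarchy: Hierarchy
    seed: Optional[int] = None

    @property
    def pat_org(self) -> np.ndarray:
        return self.pract_org[self.pat_pract]

    def n_units(self, level: str) -> int:
        return {
            "organization": self.hierarchy.organizations,
            "practitioner": self.hierarchy.n_practitioners,
            "patient": self.hierarchy.n_patients,
        }[level]

    def broadcast(self, level_from: str, level_to: str, arr: np.ndarray) -> np.ndarray:
        """Expand an array from a coarser level to a finer one."""
        if level_from == level_to:
            return arr
        if level_from == "organization" and level_to == "practitioner":
            return arr[self.pract_org]
        if level_from == "organization" and level_to == "patient":
            return arr[self.pat_org]
        if level_from == "practitioner" and level_to == "patient":
            return arr[self.pat_pract]
        raise ValueError(f"cannot broadcast {level_from} -> {level_to}")


@dataclass(frozen=True)
class TrueEffects:
    """Sample-specific true effects, keyed ``"treatment->outcome"``."""

    effects: dict

    def __getitem__(self, key: str) -> float:
        return self.effects[key]

    def as_dict(self) -> dict:
        return dict(self.effects)


# ---------------------------------------------------------------------------
# sampling


def _broadcast_parent(model, dataset_like, node_level, parent, values):
    p_level = model.level_of(parent)
    if _LEVEL_RANK[p_level] > _LEVEL_RANK[node_level]:
        raise ModelInputError(
            f"parent {parent} at level {p_level} feeds a coarser-level node"
        )
    return dataset_like.broadcast(p_level, node_level, values[parent])


def _evaluate_index(model, dataset_like, node, values):
    eq = model.equations[node]
    level = model.level_of(node)
    n = dataset_like.n_units(level)
    idx = np.full(n, eq.intercept, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        for parent, coef in zip(eq.parents, eq.coefficients):
            idx += coef * _broadcast_parent(model, dataset_like, level, parent, values)
    if not np.all(np.isfinite(idx)):
        raise SimulationNumericError(
            f"non-finite index while evaluating the equation for {node}"
        )
    return idx


def draw_population(
    model: JunctureModel, config: Optional[PopulationConfig] = None
) -> SimulatedDataset:
    """Draw one hierarchical sample from ``model``.

    The draw is fully determined by ``config.seed``.  Retains every error
    draw per unit and equation so true effects can be replayed later.
    """
    if config is None:
        config = PopulationConfig.from_model(model, seed=0)
    h = config.hierarchy
    rng = np.random.default_rng(config.seed)

    pract_org = np.repeat(np.arange(h.organizations), h.practitioners_per_organization)
    pat_pract = np.repeat(np.arange(h.n_practitioners), h.patients_per_practitioner)

    # minimal shell for broadcasting during the draw
    shell = SimulatedDataset(
        organizations=pd.DataFrame(),
        practitioners=pd.DataFrame(),
        patients=pd.DataFrame(),
        values={},
        errors={},
        pract_org=pract_org,
        pat_pract=pat_pract,
        hierarchy=h,
        seed=config.seed,
    )
    values: dict = shell.values
    errors: dict = shell.errors

    # correlated error pairs are pre-drawn, coarser level first, so that
    # finer-level members inherit the coarser unit's shock (e.g. perceived
    # leadership inheriting the organization's management-style context)
    raw_errors: dict = {}  # standard-normal draws before error_sd scaling
    for (a, b), rho in sorted(model.correlated_errors.items()):
        la, lb = model.level_of(a), model.level_of(b)
        coarse, fine = (a, b) if _LEVEL_RANK[la] <= _LEVEL_RANK[lb] else (b, a)
        raw_c = rng.standard_normal(shell.n_units(model.level_of(coarse)))
        base = shell.broadcast(
            model.level_of(coarse), model.level_of(fine), raw_c
        )
        n_f = shell.n_units(model.level_of(fine))
        raw_errors[coarse] = raw_c
        raw_errors[fine] = rho * base + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_f)

    order = model.dag.topological_order()
    for node in order:
        eq = model.equations.get(node)
        level = model.level_of(node)
        n = shell.n_units(level)
        if eq is None:
            raise ModelInputError(f"no equation for node {node}")
        if eq.link == "deterministic-sum":
            idx = _evaluate_index(model, shell, node, values)
            values[node] = idx
            errors[node] = np.zeros(n)
            continue
        raw = raw_errors.get(node)
        if raw is None:
            raw = rng.standard_normal(n)
            raw_errors[node] = raw
        idx = _evaluate_index(model, shell, node, values)
        if eq.link == "latent-utility-threshold":
            eps = raw  # scale fixed to 1
            values[node] = (idx + eps > 0).astype(float)
        else:
            eps = eq.error_sd * raw
            values[node] = idx + eps
        errors[node] = eps

    # public tables with selection masking
    gated = model.gated_nodes()
    sel = values[model.selection_node]

    def table(level, ids):
        cols = dict(ids)
        for node in sorted(n for n in model.dag.nodes if model.level_of(n) == level):
            col = values[node].astype(float).copy()
            if node in gated:
                mask = shell.broadcast("organization", level, sel) == 0
                col[mask] = np.nan
            cols[node] = col
        return pd.DataFrame(cols)

    organizations = table(
        "organization", {"organization_id": np.arange(h.organizations)}
    )
    practitioners = table(
        "practitioner",
        {
            "practitioner_id": np.arange(h.n_practitioners),
            "organization_id": pract_org,
        },
    )
    patients = table(
        "patient",
        {
            "patient_id": np.arange(h.n_patients),
            "practitioner_id": pat_pract,
            "organization_id": shell.pat_org,
        },
    )

    shell.organizations = organizations
    shell.practitioners = practitioners
    shell.patients = patients
    return shell


# ---------------------------------------------------------------------------
# replay and true effects


def replay(
    model: JunctureModel, dataset: SimulatedDataset, interventions: Mapping[str, float]
) -> dict:
    """Re-evaluate the system under ``interventions`` with errors fixed.

    Returns a complete node → array mapping.  Exogenous nodes keep their
    realized values; intervened nodes are set to the given constants;
    every other node is recomputed from its structural equation and the
    retained error draw (abduction–action–prediction).
    """
    if dataset.errors is None:
        raise ReplayContractError(
            "dataset carries no retained errors; replay is unavailable"
        )
    for node in interventions:
        if node not in model.dag.nodes:
            raise ModelInputError(f"intervention on unknown node {node!r}")

    new_values: dict = {}
    for node in model.dag.topological_order():
        level = model.level_of(node)
        n = dataset.n_units(level)
        if node in interventions:
            new_values[node] = np.full(n, float(interventions[node]))
            continue
        eq = model.equations[node]
        if not eq.parents:
            new_values[node] = dataset.values[node]
            continue
        idx = _evaluate_index(model, dataset, node, new_values)
        eps = dataset.errors[node]
        if eq.link == "latent-utility-threshold":
            new_values[node] = (idx + eps > 0).astype(float)
        elif eq.link == "deterministic-sum":
            new_values[node] = idx
        else:
            new_values[node] = idx + eps
    return new_values


def _eligible_mask(model, dataset, level):
    sel = dataset.values[model.selection_node]
    return dataset.broadcast("organization", level, sel) == 1


def _ate_by_replay(model, dataset, treatment, outcome):
    hi = replay(model, dataset, {treatment: 1.0})
    lo = replay(model, dataset, {treatment: 0.0})
    level = model.level_of(outcome)
    mask = _eligible_mask(model, dataset, level)
    if not mask.any():
        return float("nan")
    return float(np.mean(hi[outcome][mask] - lo[outcome][mask]))


def _ame_probit(model, dataset, treatment, outcome):
    """Average marginal effect of a continuous treatment on a threshold
    decision: mean of β·φ(index) at the observed covariates."""
    eq = model.equations[outcome]
    beta = dict(zip(eq.parents, eq.coefficients))[treatment]
    idx = _evaluate_index(model, dataset, outcome, dataset.values)
    mask = _eligible_mask(model, dataset, model.level_of(outcome))
    if not mask.any():
        return float("nan")
    return float(np.mean(beta * norm.pdf(idx[mask])))


#: canonical estimand roster: (treatment, outcome, truth kind)
CANONICAL_ESTIMANDS = (
    ("D2", "X4", "ate"),
    ("D2", "X5", "ate"),
    ("X4", "T1", "ame"),
    ("X5", "T1", "ame"),
    ("T1", "Y2", "ate"),
)


def true_sample_effects(model: JunctureModel, dataset: SimulatedDataset) -> TrueEffects:
    """True average effects in this particular sample.

    Average treatment effects are potential-outcome contrasts replayed
    with fixed errors; average marginal effects on decision probabilities
    use the normal-density × coefficient form at observed covariates.
    Each effect is averaged over its eligible (implementing-organization)
    population.
    """
    effects = {}
    for treatment, outcome, kind in CANONICAL_ESTIMANDS:
        key = f"{treatment}->{outcome}"
        if kind == "ate":
            effects[key] = _ate_by_replay(model, dataset, treatment, outcome)
        else:
            effects[key] = _ame_probit(model, dataset, treatment, outcome)
    return TrueEffects(effects)


# ---------------------------------------------------------------------------
# dataset bundle I/O: three CSV tables + manifest (+ optional error tables)

_TABLES = ("organizations", "practitioners", "patients")
_FLOAT_FMT = "%.12g"


def write_dataset(dataset: SimulatedDataset, path, include_errors: bool = True) -> None:
    """Write a CSV bundle: one table per hierarchy level plus a manifest.

    Selection-missing cells are written as empty fields.  With
    ``include_errors`` the retained error draws are written too, which
    makes the bundle fully replayable after :func:`read_dataset`.
    """
    os.makedirs(path, exist_ok=True)
    files = {}
    for name in _TABLES:
        fname = f"{name}.csv"
        getattr(dataset, name).to_csv(
            os.path.join(path, fname), index=False, float_format=_FLOAT_FMT
        )
        files[name] = fname
    if include_errors and dataset.errors is not None:
        err = {
            node: pd.Series(arr) for node, arr in sorted(dataset.errors.items())
        }
        by_len: dict = {}
        for node, series in err.items():
            by_len.setdefault(len(series), {})[node] = series
        for n, cols in by_len.items():
            fname = f"errors_{n}.csv"
            pd.DataFrame(cols).to_csv(
                os.path.join(path, fname), index=False, float_format=_FLOAT_FMT
            )
            files[f"errors_{n}"] = fname
    manifest = {
        "format": "juncture-dataset",
        "version": 1,
        "seed": dataset.seed,
        "hierarchy": {
            "organizations": dataset.hierarchy.organizations,
            "practitioners_per_organization": dataset.hierarchy.practitioners_per_organization,
            "patients_per_practitioner": dataset.hierarchy.patients_per_practitioner,
        },
        "files": files,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_dataset(path, model: Optional[JunctureModel] = None) -> SimulatedDataset:
    """Read a CSV bundle written by :func:`write_dataset`.

    With ``model`` given and error tables present, the complete latent
    values are rebuilt by re-running the structural equations with the
    stored errors, so the returned dataset is replayable; otherwise
    ``values`` holds the (masked) observed columns and ``errors`` is None.
    """
    mpath = os.path.join(path, "manifest.json")
    if not os.path.exists(mpath):
        raise DatasetIOError(f"no manifest.json under {path}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "juncture-dataset":
        raise DatasetIOError("manifest does not describe a juncture dataset")
    files = manifest.get("files", {})
    tables = {}
    for name in _TABLES:
        if name not in files:
            raise DatasetIOError(f"manifest missing table {name!r}")
        fpath = os.path.join(path, files[name])
        if not os.path.exists(fpath):
            raise DatasetIOError(f"manifest references missing file {files[name]!r}")
        df = pd.read_csv(fpath)
        for col in df.columns:
            if not col.endswith("_id"):
                df[col] = df[col].astype(float)
        tables[name] = df

    h = manifest["hierarchy"]
    hierarchy = Hierarchy(
        int(h["organizations"]),
        int(h["practitioners_per_organization"]),
        int(h["patients_per_practitioner"]),
    )
    for name, expected in (
        ("organizations", hierarchy.organizations),
        ("practitioners", hierarchy.n_practitioners),
        ("patients", hierarchy.n_patients),
    ):
        if len(tables[name]) != expected:
            raise DatasetIOError(
                f"{name} table has {len(tables[name])} rows, manifest implies {expected}"
            )
    pract_org = tables["practitioners"]["organization_id"].to_numpy()
    pat_pract = tables["patients"]["practitioner_id"].to_numpy()
    if pract_org.min(initial=0) < 0 or (
        len(pract_org) and pract_org.max() >= hierarchy.organizations
    ):
        raise DatasetIOError("practitioner row references unknown organization")
    if len(pat_pract) and (
        pat_pract.min() < 0 or pat_pract.max() >= hierarchy.n_practitioners
    ):
        raise DatasetIOError("patient row references unknown practitioner")

    errors: Optional[dict] = None
    err_files = [v for k, v in files.items() if k.startswith("errors_")]
    if err_files:
        errors = {}
        for fname in err_files:
            fpath = os.path.join(path, fname)
            if not os.path.exists(fpath):
                raise DatasetIOError(f"manifest references missing file {fname!r}")
            df = pd.read_csv(fpath)
            for col in df.columns:
                errors[col] = df[col].to_numpy()

    values = {}
    for name in _TABLES:
        for col in tables[name].columns:
            if not col.endswith("_id"):
                values[col] = tables[name][col].to_numpy(dtype=float)

    dataset = SimulatedDataset(
        organizations=tables["organizations"],
        practitioners=tables["practitioners"],
        patients=tables["patients"],
        values=values,
        errors=errors,
        pract_org=pract_org,
        pat_pract=pat_pract,
        hierarchy=hierarchy,
        seed=manifest.get("seed"),
    )
    if model is not None and errors is not None:
        # rebuild complete latent values from exogenous columns + errors
        complete: dict = {}
        for node in model.dag.topological_order():
            eq = model.equations[node]
            if not eq.parents:
                complete[node] = values[node]
                continue
            idx = _evaluate_index(model, dataset, node, complete)
            if eq.link == "latent-utility-threshold":
                complete[node] = (idx + errors[node] > 0).astype(float)
            elif eq.link == "deterministic-sum":
                complete[node] = idx
            else:
                complete[node] = idx + errors[node]
        dataset.values = complete
    return dataset
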
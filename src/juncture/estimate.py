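"""Estimation of implementation and intervention effects.

Continuous outcomes are fitted by ordinary least squares, binary decisions
by probit maximum likelihood with the effect reported as an average
marginal effect (AME) on the probability scale — the scale on which the
sample truths are defined.  Each estimand is fitted under a *short*
specification (a certified back-door-minimal covariate set) or a *full*
specification (every parent of the outcome), the latter trading no change
in bias for lower variance.  Organization-level treatments get
cluster-robust standard errors at the organization level; everything else
gets heteroskedasticity-robust ones.  Estimation uses only rows observable
in the system, i.e. units in implementing organizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .causal_graph import IdentificationQuery, is_valid_backdoor, minimal_adjustment_sets
from .model_spec import CANONICAL_ADJUSTMENT_SETS, JunctureModel
from .simulate import SimulatedDataset

__all__ = [
    "EstimandSpec",
    "EffectEstimate",
    "IdentificationError",
    "FitError",
    "EstimationNumericError",
    "build_specification",
    "fit_linear",
    "fit_probit_ame",
    "fit",
    "estimates_to_frame",
]


class IdentificationError(ValueError):
    """No valid adjustment set, or no eligible observations."""


class FitError(RuntimeError):
    """Degenerate design: exact collinearity or perfect separation."""


class EstimationNumericError(ArithmeticError):
    """Optimizer failed to converge."""


@dataclass(frozen=True)
class EstimandSpec:
    estimand_id: str
    treatment: str
    outcome: str
    covariates: tuple
    estimator: str  # "linear" | "probit-ame"
    specification: str  # "short" | "full"
    cluster_level: str = "none"  # "organization" | "none"

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.treatment in self.covariates or self.outcome in self.covariates:
            raise IdentificationError(
                "covariates must exclude treatment and outcome"
            )
        if self.estimator not in ("linear", "probit-ame"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.specification not in ("short", "full"):
            raise ValueError(f"unknown specification {self.specification!r}")
        if self.cluster_level not in ("organization", "none"):
            raise ValueError(f"unknown cluster level {self.cluster_level!r}")


@dataclass(frozen=True)
class EffectEstimate:
    estimand_id: str
    estimate: float
    se: float
    n_used: int
    specification: str
    degenerate: bool = False


def build_specification(
    model: JunctureModel, treatment: str, outcome: str, mode: str
) -> EstimandSpec:
    """Construct a certified estimand specification.

    Short mode prefers the adjustment set named in the system's
    identification discussion when it is valid on the encoded DAG (checked
    by the back-door criterion, selection node conditioned), otherwise the
    first minimal set in deterministic order.  Full mode uses all parents
    of the outcome except the treatment, plus any short-set member that is
    not a parent.  Raises :class:`IdentificationError` when no valid
    adjustment set exists.
    """
    if mode not in ("short", "full"):
        raise ValueError(f"unknown specification mode {mode!r}")
    dag = model.dag
    sel = model.selection_node

    named = CANONICAL_ADJUSTMENT_SETS.get((treatment, outcome))
    short: Optional[tuple] = None
    if named is not None and set(named) <= dag.observed_nodes():
        q = IdentificationQuery(treatment, outcome, frozenset(named), sel)
        if is_valid_backdoor(dag, q):
            short = tuple(sorted(named))
    if short is None:
        minimal = minimal_adjustment_sets(dag, treatment, outcome, selection=sel)
        if not minimal:
            raise IdentificationError(
                f"no valid back-door adjustment set for {treatment}->{outcome}"
            )
        short = tuple(sorted(minimal[0]))

    if mode == "short":
        covariates = short
    else:
        parents = dag.parents(outcome) - {treatment}
        covariates = tuple(sorted(parents | set(short)))

    estimator = (
        "probit-ame" if model.kind_of(outcome) == "binary-decision" else "linear"
    )
    cluster = (
        "organization" if model.level_of(treatment) == "organization" else "none"
    )
    return EstimandSpec(
        estimand_id=f"{treatment}->{outcome}",
        treatment=treatment,
        outcome=outcome,
        covariates=covariates,
        estimator=estimator,
        specification=mode,
        cluster_level=cluster,
    )


def _certify_short(model: JunctureModel, spec: EstimandSpec) -> None:
    """Hard assertion: a short specification must be a valid back-door set."""
    if spec.specification != "short":
        return
    q = IdentificationQuery(
        spec.treatment, spec.outcome, frozenset(spec.covariates), model.selection_node
    )
    if not is_valid_backdoor(model.dag, q):
        raise IdentificationError(
            f"short specification {spec.covariates} is not a valid back-door "
            f"set for {spec.estimand_id}"
        )


def _analysis_frame(model: JunctureModel, dataset: SimulatedDataset, spec: EstimandSpec):
    """Rows at the outcome's level with treatment/covariates broadcast in,
    restricted to complete (post-selection observable) cases."""
    level = model.level_of(spec.outcome)
    n = dataset.n_units(level)
    cols = {"__org__": dataset.broadcast(
        "organization", level, np.arange(dataset.hierarchy.organizations)
    ) if level != "organization" else np.arange(n)}
    needed = (spec.outcome, spec.treatment) + spec.covariates
    gated = model.gated_nodes()
    sel = dataset.values[model.selection_node]
    for node in needed:
        arr = dataset.broadcast(
            model.level_of(node), level, dataset.values[node]
        ).astype(float).copy()
        if node in gated:
            arr[dataset.broadcast("organization", level, sel) == 0] = np.nan
        cols[node] = arr
    frame = pd.DataFrame(cols).dropna()
    return frame


def _design(frame: pd.DataFrame, spec: EstimandSpec):
    X = frame[[spec.treatment, *spec.covariates]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame)), X])
    names = ["const", spec.treatment, *spec.covariates]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column set via QR pivoting on the gram matrix
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise FitError(f"exact collinearity among design columns {bad or names}")
    return X, names


def _fit_kwargs(spec: EstimandSpec, frame: pd.DataFrame) -> dict:
    if spec.cluster_level == "organization":
        groups = frame["__org__"].to_numpy()
        # sandwich with small-sample cluster correction G/(G-1)
        return {
            "cov_type": "cluster",
            "cov_kwds": {"groups": groups, "use_correction": True},
        }
    if spec.estimator == "linear":
        return {"cov_type": "HC1", "cov_kwds": {}}
    return {}  # probit without clustering: plain MLE covariance


def fit_linear(
    model: JunctureModel, dataset: SimulatedDataset, spec: EstimandSpec
) -> EffectEstimate:
    """OLS on eligible rows; reports the treatment coefficient."""
    if spec.estimator != "linear":
        raise ValueError("fit_linear requires a linear estimand spec")
    _certify_short(model, spec)
    frame = _analysis_frame(model, dataset, spec)
    if len(frame) == 0:
        raise IdentificationError(f"no eligible rows for {spec.estimand_id}")
    if len(frame) < len(spec.covariates) + 2:
        raise IdentificationError(
            f"{spec.estimand_id}: {len(frame)} rows cannot support "
            f"{len(spec.covariates) + 2} parameters"
        )
    X, names = _design(frame, spec)
    y = frame[spec.outcome].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit(**_fit_kwargs(spec, frame))
    j = names.index(spec.treatment)
    est = float(res.params[j])
    se = float(res.bse[j])
    degenerate = not np.isfinite(se) or se <= 0
    return EffectEstimate(
        spec.estimand_id, est, 0.0 if degenerate else se, len(frame),
        spec.specification, degenerate=degenerate,
    )


def fit_probit_ame(
    model: JunctureModel, dataset: SimulatedDataset, spec: EstimandSpec
) -> EffectEstimate:
    """Probit MLE with the treatment's average marginal effect.

    Continuous treatments report the density-weighted coefficient averaged
    over eligible rows; binary treatments the discrete probability
    contrast.  Standard errors come from the delta method on the fitted
    covariance (cluster-aggregated when the spec requests it).
    """
    if spec.estimator != "probit-ame":
        raise ValueError("fit_probit_ame requires a probit-ame estimand spec")
    _certify_short(model, spec)
    frame = _analysis_frame(model, dataset, spec)
    if len(frame) == 0:
        raise IdentificationError(f"no eligible rows for {spec.estimand_id}")
    y = frame[spec.outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError(
            f"{spec.estimand_id}: outcome takes a single value "
            f"({classes[0]:g}) among eligible rows"
        )
    X, names = _design(frame, spec)
    probit = sm.Probit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = probit.fit(
                method="newton", tol=1e-8, maxiter=200, disp=0,
                **_fit_kwargs(spec, frame),
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise FitError(f"{spec.estimand_id}: perfect separation") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationNumericError(
            f"{spec.estimand_id}: probit did not converge within 200 "
            f"iterations (retvals: {res.mle_retvals})"
        )

    j = names.index(spec.treatment)
    treat_vals = frame[spec.treatment].to_numpy(dtype=float)
    is_binary = set(np.unique(treat_vals)) <= {0.0, 1.0}
    margeff = res.get_margeff(at="overall", method="dydx", dummy=is_binary)
    # margeff drops the constant: exogenous-variable index j-1
    est = float(margeff.margeff[j - 1])
    se = float(margeff.margeff_se[j - 1])
    return EffectEstimate(
        spec.estimand_id, est, se, len(frame), spec.specification
    )


def fit(
    model: JunctureModel, dataset: SimulatedDataset, spec: EstimandSpec
) -> EffectEstimate:
    """Dispatch on the spec's estimator."""
    if spec.estimator == "linear":
        return fit_linear(model, dataset, spec)
    return fit_probit_ame(model, dataset, spec)


def estimates_to_frame(estimates, seed=None) -> pd.DataFrame:
    """Tidy export: estimand, specification, estimate, SE, n_used, seed."""
    rows = [
        {
            "estimand": e.estimand_id,
            "specification": e.specification,
            "estimate": e.estimate,
            "se": e.se,
            "n_used": e.n_used,
            "seed": seed,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
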
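"""The canonical CBT implementation system and its validation.

Encodes a hypothetical regional scale-up of cognitive behavioral therapy
(CBT) for youth anxiety as a multilevel decision-juncture model: state
funding is available, each organization decides whether to implement at
all (D1), implementing organizations choose a basic or enhanced support
strategy (D2), practitioners form perceptions of feasibility (X4) and
appropriateness (X5) and decide patient by patient whether to assign CBT
(T1), and assignment moves the follow-up symptom score (Y2).

Variables
---------
Organization level
    Z1 intra-organizational networks, Z2 management style, Z3
    organizational structure, B1 perceived strength of evidence, W1/W2
    anticipated costs of the two strategies, W = W1 + W2 aggregate cost,
    D1 implement at all, D2 enhanced (1) vs. basic (0) strategy.
Practitioner level
    X1 age, X2 perceived leadership, X3 tenure, X4 perceived feasibility,
    X5 perceived appropriateness.
Patient level
    V1 age, V2 gender, V3 socio-economic status, Y1 baseline score,
    T1 practitioner assigns CBT, Y2 follow-up score.

Management style and perceived leadership share an unobserved cause
(Z2 ↔ X2 correlated errors), which is what makes X2 a genuine confounder
of the strategy's effect on practitioner perceptions.

Decisions are latent-utility thresholds with standard-normal errors, so a
probit regression is the correctly specified estimator; continuous nodes
are linear in their parents with normal errors; W is a deterministic sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import yaml

from .causal_graph import (
    CausalDAG,
    GraphInputError,
    IdentificationQuery,
    build_dag,
    is_valid_backdoor,
    minimal_adjustment_sets,
)

__all__ = [
    "NodeSpec",
    "StructuralEquation",
    "Hierarchy",
    "JunctureModel",
    "ModelInputError",
    "Claim",
    "ClaimReport",
    "canonical_cbt_model",
    "validate_claims",
    "read_model",
    "write_model",
    "CANONICAL_ADJUSTMENT_SETS",
]

LEVELS = ("organization", "practitioner", "patient", "intervention")
KINDS = ("continuous", "binary-decision", "deterministic-aggregate")
LINKS = ("linear", "latent-utility-threshold", "deterministic-sum")


class ModelInputError(ValueError):
    """Schema or invariant violation in a juncture model description."""


@dataclass(frozen=True)
class NodeSpec:
    id: str
    level: str
    kind: str
    label: str = ""

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ModelInputError(f"{self.id}: unknown level {self.level!r}")
        if self.kind not in KINDS:
            raise ModelInputError(f"{self.id}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class StructuralEquation:
    """One node's structural assignment: child = f(parents) + error.

    ``latent-utility-threshold`` children are binary decisions
    d = 1[intercept + Σ coef·parent + ε > 0] with ε ~ N(0, 1); the unit
    error scale identifies the index coefficients and makes probit the
    matching estimator.  ``deterministic-sum`` children carry no error.
    """

    child: str
    parents: tuple
    intercept: float
    coefficients: tuple
    link: str
    error_sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if self.link not in LINKS:
            raise ModelInputError(f"{self.child}: unknown link {self.link!r}")
        if len(self.parents) != len(self.coefficients):
            raise ModelInputError(
                f"{self.child}: {len(self.parents)} parents but "
                f"{len(self.coefficients)} coefficients"
            )
        if self.error_sd < 0:
            raise ModelInputError(f"{self.child}: negative error_sd")
        if self.link == "latent-utility-threshold" and self.error_sd != 1.0:
            raise ModelInputError(
                f"{self.child}: latent-utility-threshold error_sd is fixed to 1"
            )


@dataclass(frozen=True)
class Hierarchy:
    organizations: int
    practitioners_per_organization: int
    patients_per_practitioner: int

    def __post_init__(self):
        for name, v in (
            ("organizations", self.organizations),
            ("practitioners_per_organization", self.practitioners_per_organization),
            ("patients_per_practitioner", self.patients_per_practitioner),
        ):
            if not isinstance(v, int) or v <= 0:
                raise ModelInputError(f"hierarchy count {name} must be a positive int")

    @property
    def n_practitioners(self) -> int:
        return self.organizations * self.practitioners_per_organization

    @property
    def n_patients(self) -> int:
        return self.n_practitioners * self.patients_per_practitioner


@dataclass(frozen=True)
class JunctureModel:
    """Executable multilevel decision-juncture system."""

    dag: CausalDAG
    node_specs: Mapping[str, NodeSpec]
    equations: Mapping[str, StructuralEquation]
    correlated_errors: Mapping[tuple, float]
    hierarchy: Hierarchy
    selection_node: str = "D1"

    def __post_init__(self):
        object.__setattr__(self, "node_specs", dict(self.node_specs))
        object.__setattr__(
            self,
            "correlated_errors",
            {
                (min(a, b), max(a, b)): float(r)
                for (a, b), r in dict(self.correlated_errors).items()
            },
        )
        object.__setattr__(self, "equations", dict(self.equations))
        self._validate()

    def _validate(self):
        if set(self.node_specs) != set(self.dag.nodes):
            raise ModelInputError("node_specs must cover exactly the DAG nodes")
        if self.selection_node not in self.dag.nodes:
            raise ModelInputError(f"unknown selection node {self.selection_node!r}")
        for nid, eq in self.equations.items():
            if nid not in self.dag.nodes:
                raise ModelInputError(f"equation for undeclared node {nid!r}")
            if eq.child != nid:
                raise ModelInputError(f"equation keyed {nid!r} has child {eq.child!r}")
            dag_parents = self.dag.parents(nid)
            if set(eq.parents) != dag_parents:
                raise ModelInputError(
                    f"{nid}: equation parents {sorted(eq.parents)} do not match "
                    f"DAG parents {sorted(dag_parents)}"
                )
            kind = self.node_specs[nid].kind
            if eq.link == "latent-utility-threshold" and kind != "binary-decision":
                raise ModelInputError(f"{nid}: threshold link on non-decision node")
            if eq.link == "linear" and kind != "continuous":
                raise ModelInputError(f"{nid}: linear link on non-continuous node")
            if eq.link == "deterministic-sum" and kind != "deterministic-aggregate":
                raise ModelInputError(f"{nid}: sum link on non-aggregate node")
        endogenous = {n for n in self.dag.nodes if self.dag.parents(n)}
        missing = endogenous - set(self.equations)
        if missing:
            raise ModelInputError(f"nodes without equations: {sorted(missing)}")
        ce_keys = set(self.correlated_errors)
        if ce_keys != set(self.dag.bidirected_edges):
            raise ModelInputError(
                "correlated_errors keys must equal the DAG's bidirected edges"
            )
        for pair, rho in self.correlated_errors.items():
            if not -1.0 < rho < 1.0:
                raise ModelInputError(f"correlation for {pair} outside (-1, 1)")

    # -- convenience -------------------------------------------------------
    def level_of(self, node: str) -> str:
        return self.node_specs[node].level

    def kind_of(self, node: str) -> str:
        return self.node_specs[node].kind

    def exogenous_nodes(self) -> list:
        return sorted(n for n in self.dag.nodes if not self.dag.parents(n))

    def gated_nodes(self) -> set:
        """Nodes that exist only on the implementing (selection = 1) branch.

        Decision junctures downstream of the selection node, plus all of
        their descendants: non-implementing organizations make no strategy
        choice, practitioners there form no treatment-specific perceptions
        and assign no patients.
        """
        seeds = {
            n
            for n, spec in self.node_specs.items()
            if spec.kind == "binary-decision"
            and n != self.selection_node
            and self.dag.parents(n)
        }
        gated = set(seeds)
        for s in seeds:
            gated |= self.dag.descendants(s)
        return gated


# ---------------------------------------------------------------------------
# canonical model

_CANONICAL_NODES = [
    NodeSpec("Z1", "organization", "continuous", "intra-organizational networks"),
    NodeSpec("Z2", "organization", "continuous", "management style"),
    NodeSpec("Z3", "organization", "continuous", "organizational structure"),
    NodeSpec("B1", "organization", "continuous", "perceived strength of evidence"),
    NodeSpec("W1", "organization", "continuous", "anticipated cost, basic strategy"),
    NodeSpec("W2", "organization", "continuous", "anticipated cost, enhanced strategy"),
    NodeSpec("W", "organization", "deterministic-aggregate", "aggregate cost"),
    NodeSpec("D1", "organization", "binary-decision", "implement CBT at all"),
    NodeSpec("D2", "organization", "binary-decision", "enhanced vs. basic strategy"),
    NodeSpec("X1", "practitioner", "continuous", "practitioner age"),
    NodeSpec("X2", "practitioner", "continuous", "perceived leadership"),
    NodeSpec("X3", "practitioner", "continuous", "tenure in current job"),
    NodeSpec("X4", "practitioner", "continuous", "perceived feasibility"),
    NodeSpec("X5", "practitioner", "continuous", "perceived appropriateness"),
    NodeSpec("V1", "patient", "continuous", "patient age"),
    NodeSpec("V2", "patient", "binary-decision", "patient gender"),
    NodeSpec("V3", "patient", "continuous", "socio-economic status"),
    NodeSpec("Y1", "patient", "continuous", "baseline symptom score"),
    NodeSpec("T1", "patient", "binary-decision", "practitioner assigns CBT"),
    NodeSpec("Y2", "patient", "continuous", "follow-up symptom score"),
]

_CANONICAL_DIRECTED = [
    ("Z1", "D1"), ("Z2", "D1"), ("Z3", "D1"), ("B1", "D1"), ("W", "D1"),
    ("W1", "W"), ("W2", "W"),
    ("Z1", "D2"), ("Z2", "D2"), ("B1", "D2"), ("W1", "D2"), ("W2", "D2"),
    ("D2", "X4"), ("D2", "X5"),
    ("Z1", "X4"), ("Z1", "X5"),
    ("X1", "X4"), ("X1", "X5"),
    ("X2", "X4"), ("X2", "X5"),
    ("Z1", "T1"), ("X2", "T1"), ("X3", "T1"), ("X4", "T1"), ("X5", "T1"),
    ("V1", "T1"), ("V2", "T1"), ("Y1", "T1"),
    ("V3", "Y1"),
    ("T1", "Y2"), ("V1", "Y2"), ("V2", "Y2"), ("V3", "Y2"), ("Y1", "Y2"),
]

_CANONICAL_BIDIRECTED = [("Z2", "X2")]

# default structural coefficients: moderate confounding (0.3) so that
# omitted-variable negative controls show visible bias while every decision
# probability stays interior; strategy effect on perceptions 0.5; treatment
# effect on the follow-up score 1.0.
_CANONICAL_EQUATIONS = [
    # exogenous draws (no parents): value = intercept + error
    StructuralEquation("Z1", (), 0.0, (), "linear", 1.0),
    StructuralEquation("Z2", (), 0.0, (), "linear", 1.0),
    StructuralEquation("Z3", (), 0.0, (), "linear", 1.0),
    StructuralEquation("B1", (), 0.0, (), "linear", 1.0),
    StructuralEquation("W1", (), 0.0, (), "linear", 1.0),
    StructuralEquation("W2", (), 0.0, (), "linear", 1.0),
    StructuralEquation("X1", (), 0.0, (), "linear", 1.0),
    StructuralEquation("X2", (), 0.0, (), "linear", 1.0),
    StructuralEquation("X3", (), 0.0, (), "linear", 1.0),
    StructuralEquation("V1", (), 0.0, (), "linear", 1.0),
    StructuralEquation("V2", (), 0.0, (), "latent-utility-threshold", 1.0),
    StructuralEquation("V3", (), 0.0, (), "linear", 1.0),
    # aggregate cost
    StructuralEquation("W", ("W1", "W2"), 0.0, (1.0, 1.0), "deterministic-sum", 0.0),
    # organizational decisions
    StructuralEquation(
        "D1",
        ("Z1", "Z2", "Z3", "B1", "W"),
        0.0,
        (0.3, 0.3, 0.3, 0.4, -0.3),
        "latent-utility-threshold",
    ),
    StructuralEquation(
        "D2",
        ("Z1", "Z2", "B1", "W1", "W2"),
        0.0,
        (0.3, 0.3, 0.4, 0.3, -0.3),
        "latent-utility-threshold",
    ),
    # practitioner perceptions (error_sd 0.5: perceptions largely explained
    # by strategy, networks, age and leadership; keeps organization-level
    # Monte Carlo noise moderate)
    StructuralEquation(
        "X4", ("D2", "Z1", "X1", "X2"), 0.0, (0.5, 0.3, 0.3, 0.3), "linear", 0.5
    ),
    StructuralEquation(
        "X5", ("D2", "Z1", "X1", "X2"), 0.0, (0.5, 0.3, 0.3, 0.3), "linear", 0.5
    ),
    # patient baseline and treatment decision
    StructuralEquation("Y1", ("V3",), 0.0, (0.3,), "linear", 1.0),
    StructuralEquation(
        "T1",
        ("Z1", "X2", "X3", "X4", "X5", "V1", "V2", "Y1"),
        0.0,
        (0.3, 0.3, 0.3, 0.4, 0.3, 0.3, 0.3, 0.3),
        "latent-utility-threshold",
    ),
    # follow-up outcome
    StructuralEquation(
        "Y2", ("T1", "V1", "V2", "V3", "Y1"), 0.0, (1.0, 0.3, 0.3, 0.3, 0.5), "linear", 1.0
    ),
]

_CANONICAL_CORRELATED_ERRORS = {("Z2", "X2"): 0.5}

_CANONICAL_HIERARCHY = Hierarchy(40, 5, 30)  # 6000 patients

#: Adjustment sets named in the identification discussion of the system;
#: used as the preferred short specification when valid on the encoded DAG.
CANONICAL_ADJUSTMENT_SETS = {
    ("D2", "X4"): ("Z1", "X2"),
    ("D2", "X5"): ("Z1", "X2"),
    ("X4", "T1"): ("Z1", "X2", "X5"),
    ("X5", "T1"): ("Z1", "X2", "X4"),
    ("T1", "Y2"): ("V1", "V2", "Y1"),
}


def canonical_cbt_model(overrides: Optional[Mapping] = None) -> JunctureModel:
    """Build the canonical CBT implementation system.

    ``overrides`` may contain:

    ``hierarchy``
        mapping with any of ``organizations``,
        ``practitioners_per_organization``, ``patients_per_practitioner``.
    ``equations``
        mapping child id → {``intercept``: float, ``error_sd``: float,
        ``coefficients``: {parent id: float}}.
    ``correlated_errors``
        mapping (a, b) pair → correlation.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - {"hierarchy", "equations", "correlated_errors"}
    if unknown:
        raise ModelInputError(f"unknown override sections: {sorted(unknown)}")

    hierarchy = _CANONICAL_HIERARCHY
    if "hierarchy" in overrides:
        h = dict(overrides["hierarchy"])
        bad = set(h) - {
            "organizations",
            "practitioners_per_organization",
            "patients_per_practitioner",
        }
        if bad:
            raise ModelInputError(f"unknown hierarchy fields: {sorted(bad)}")
        hierarchy = replace(hierarchy, **h)

    equations = {eq.child: eq for eq in _CANONICAL_EQUATIONS}
    for child, spec in dict(overrides.get("equations", {})).items():
        if child not in equations:
            raise ModelInputError(f"override for unknown equation {child!r}")
        eq = equations[child]
        spec = dict(spec)
        coef_over = dict(spec.pop("coefficients", {}))
        bad_parents = set(coef_over) - set(eq.parents)
        if bad_parents:
            raise ModelInputError(
                f"{child}: coefficient override for non-parents {sorted(bad_parents)}"
            )
        coefs = tuple(
            coef_over.get(p, c) for p, c in zip(eq.parents, eq.coefficients)
        )
        allowed = {"intercept", "error_sd"}
        bad = set(spec) - allowed
        if bad:
            raise ModelInputError(f"{child}: unknown equation fields {sorted(bad)}")
        equations[child] = replace(eq, coefficients=coefs, **spec)

    correlated = dict(_CANONICAL_CORRELATED_ERRORS)
    for pair, rho in dict(overrides.get("correlated_errors", {})).items():
        key = (min(pair), max(pair))
        if key not in correlated:
            raise ModelInputError(f"override for unknown correlated-error pair {pair}")
        correlated[key] = float(rho)

    dag = build_dag(
        [n.id for n in _CANONICAL_NODES], _CANONICAL_DIRECTED, _CANONICAL_BIDIRECTED
    )
    return JunctureModel(
        dag=dag,
        node_specs={n.id: n for n in _CANONICAL_NODES},
        equations=equations,
        correlated_errors=correlated,
        hierarchy=hierarchy,
        selection_node="D1",
    )


# ---------------------------------------------------------------------------
# claim validation


@dataclass(frozen=True)
class Claim:
    claim_id: str
    description: str
    passed: bool
    details: str = ""


@dataclass(frozen=True)
class ClaimReport:
    claims: tuple

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.claims)

    def __getitem__(self, claim_id: str) -> Claim:
        for c in self.claims:
            if c.claim_id == claim_id:
                return c
        raise KeyError(claim_id)

    def summary(self) -> str:
        lines = []
        for c in self.claims:
            mark = "PASS" if c.passed else "FAIL"
            lines.append(f"[{mark}] {c.claim_id}: {c.description}")
            if c.details:
                lines.append(f"       {c.details}")
        return "\n".join(lines)


def _check_set(dag, treatment, outcome, zs, selection):
    q = IdentificationQuery(treatment, outcome, frozenset(zs), selection)
    return is_valid_backdoor(dag, q)


def validate_claims(model: JunctureModel) -> ClaimReport:
    """Certify the encoded DAG against every identification statement the
    system is built to satisfy.

    All queries condition on the selection node (implementation decision):
    post-selection variables only exist in implementing organizations.
    """
    dag = model.dag
    sel = model.selection_node
    claims = []

    ok_x4 = _check_set(dag, "D2", "X4", ("Z1", "X2"), sel)
    ok_x5 = _check_set(dag, "D2", "X5", ("Z1", "X2"), sel)
    claims.append(
        Claim(
            "a",
            "{Z1, X2} is a valid back-door set for D2→X4 and D2→X5",
            ok_x4 and ok_x5,
            f"D2→X4: {ok_x4}, D2→X5: {ok_x5}",
        )
    )

    ok_b = _check_set(dag, "X4", "T1", ("Z1", "X2", "X5"), sel)
    claims.append(
        Claim("b", "{Z1, X2, X5} is a valid back-door set for X4→T1", ok_b)
    )

    ok_c = _check_set(dag, "X5", "T1", ("Z1", "X2", "X4"), sel)
    claims.append(
        Claim(
            "c",
            "the symmetric set {Z1, X2, X4} is a valid back-door set for X5→T1",
            ok_c,
        )
    )

    ok_d = _check_set(dag, "T1", "Y2", ("V1", "V2", "Y1"), sel)
    claims.append(
        Claim("d", "{V1, V2, Y1} is a valid back-door set for T1→Y2", ok_d)
    )

    minimal = minimal_adjustment_sets(dag, "X4", "T1", selection=sel)
    precision_only = {"X3", "V1", "V2", "Y1"}
    used = precision_only & set().union(*map(set, minimal)) if minimal else set()
    claims.append(
        Claim(
            "e",
            "X3, V1, V2, Y1 are precision covariates for X4→T1: no minimal "
            "adjustment set contains them",
            bool(minimal) and not used,
            f"minimal sets: {[list(m) for m in minimal]}",
        )
    )
    return ClaimReport(tuple(claims))


# ---------------------------------------------------------------------------
# model file I/O (JSON or YAML by extension)


def _model_to_payload(model: JunctureModel) -> dict:
    return {
        "nodes": [
            {"id": n.id, "level": n.level, "kind": n.kind, "label": n.label}
            for n in sorted(model.node_specs.values(), key=lambda s: s.id)
        ],
        "edges": [list(e) for e in sorted(model.dag.directed_edges)],
        "bidirected": [
            {"pair": list(pair), "correlation": rho}
            for pair, rho in sorted(model.correlated_errors.items())
        ],
        "equations": [
            {
                "child": eq.child,
                "parents": list(eq.parents),
                "intercept": eq.intercept,
                "coefficients": list(eq.coefficients),
                "link": eq.link,
                "error_sd": eq.error_sd,
            }
            for eq in sorted(model.equations.values(), key=lambda e: e.child)
        ],
        "hierarchy": {
            "organizations": model.hierarchy.organizations,
            "practitioners_per_organization": model.hierarchy.practitioners_per_organization,
            "patients_per_practitioner": model.hierarchy.patients_per_practitioner,
        },
        "selection_node": model.selection_node,
    }


def _payload_to_model(payload: Mapping) -> JunctureModel:
    try:
        node_specs = {
            n["id"]: NodeSpec(n["id"], n["level"], n["kind"], n.get("label", ""))
            for n in payload["nodes"]
        }
        bidirected = [tuple(b["pair"]) for b in payload.get("bidirected", [])]
        correlated = {
            tuple(sorted(b["pair"])): float(b["correlation"])
            for b in payload.get("bidirected", [])
        }
        dag = build_dag(list(node_specs), payload["edges"], bidirected)
        equations = {}
        for e in payload["equations"]:
            eq = StructuralEquation(
                e["child"],
                tuple(e["parents"]),
                float(e["intercept"]),
                tuple(e["coefficients"]),
                e["link"],
                float(e.get("error_sd", 1.0)),
            )
            equations[eq.child] = eq
        h = payload["hierarchy"]
        hierarchy = Hierarchy(
            int(h["organizations"]),
            int(h["practitioners_per_organization"]),
            int(h["patients_per_practitioner"]),
        )
    except KeyError as exc:
        raise ModelInputError(f"missing model field: {exc}") from exc
    except (GraphInputError, TypeError) as exc:
        raise ModelInputError(str(exc)) from exc
    return JunctureModel(
        dag=dag,
        node_specs=node_specs,
        equations=equations,
        correlated_errors=correlated,
        hierarchy=hierarchy,
        selection_node=payload.get("selection_node", "D1"),
    )


def write_model(model: JunctureModel, path) -> None:
    """Serialize a model to JSON or YAML (chosen by file extension)."""
    payload = _model_to_payload(model)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def read_model(path) -> JunctureModel:
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    if not isinstance(payload, Mapping):
        raise ModelInputError("model file must contain a mapping at top level")
    return _payload_to_model(payload)
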
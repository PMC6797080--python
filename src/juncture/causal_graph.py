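"""Structural causal DAGs and graphical identification queries.

A :class:`CausalDAG` carries directed edges (causal effects) and bidirected
edges (unobserved correlated errors between two variables).  Bidirected
edges are given latent-common-parent semantics: before any path analysis
the graph is expanded with a fresh hidden node ``L`` and edges ``L→A``,
``L→B`` for every pair ``A↔B``.  Hidden nodes are never eligible for
adjustment and never appear in query results.

The module answers the identification queries needed for covariate
selection in decision-juncture models: d-separation, back-door validity of
an adjustment set (optionally with a selection node that is always treated
as conditioned on, e.g. an organization's decision to implement at all),
and enumeration of all inclusion-minimal valid adjustment sets.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = [
    "CausalDAG",
    "IdentificationQuery",
    "GraphInputError",
    "GraphStructureError",
    "build_dag",
    "d_separated",
    "is_valid_backdoor",
    "minimal_adjustment_sets",
    "read_edgelist",
    "write_edgelist",
    "dag_to_json",
    "dag_from_json",
]

_LATENT_PREFIX = "__latent__"


class GraphInputError(ValueError):
    """Malformed input to a graph operation (unknown node, bad query)."""


class GraphStructureError(ValueError):
    """Structural violation such as a directed cycle or a self-loop."""


@dataclass(frozen=True)
class CausalDAG:
    """A causal DAG with directed and bidirected (correlated-error) edges."""

    nodes: frozenset
    directed_edges: frozenset  # of (parent, child) tuples
    bidirected_edges: frozenset  # of canonical (a, b) tuples, a < b

    def parents(self, node: str) -> set:
        self._require(node)
        return {a for a, b in self.directed_edges if b == node}

    def children(self, node: str) -> set:
        self._require(node)
        return {b for a, b in self.directed_edges if a == node}

    def descendants(self, node: str) -> set:
        """Strict descendants of ``node`` along directed edges."""
        self._require(node)
        return set(nx.descendants(self._digraph(), node))

    def ancestors(self, node: str) -> set:
        self._require(node)
        return set(nx.ancestors(self._digraph(), node))

    def topological_order(self) -> list:
        # lexicographic tie-break: stable across processes and hash seeds
        return list(nx.lexicographical_topological_sort(self._digraph()))

    def latent_expansion(self) -> "CausalDAG":
        """Replace every bidirected edge by a fresh hidden common parent."""
        if not self.bidirected_edges:
            return self
        nodes = set(self.nodes)
        directed = set(self.directed_edges)
        for a, b in sorted(self.bidirected_edges):
            latent = f"{_LATENT_PREFIX}{a}__{b}"
            nodes.add(latent)
            directed.add((latent, a))
            directed.add((latent, b))
        return CausalDAG(frozenset(nodes), frozenset(directed), frozenset())

    def remove_outgoing(self, node: str) -> "CausalDAG":
        """Copy of the graph with all directed arrows out of ``node`` removed."""
        self._require(node)
        directed = frozenset(e for e in self.directed_edges if e[0] != node)
        return CausalDAG(self.nodes, directed, self.bidirected_edges)

    def observed_nodes(self) -> set:
        return {n for n in self.nodes if not n.startswith(_LATENT_PREFIX)}

    def _require(self, node: str) -> None:
        if node not in self.nodes:
            raise GraphInputError(f"unknown node: {node!r}")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g


@dataclass(frozen=True)
class IdentificationQuery:
    """A back-door query: treatment, outcome, candidate adjustment set.

    ``selection`` names a node that is always treated as conditioned on
    (post-selection estimands only exist on one branch of that decision).
    """

    treatment: str
    outcome: str
    conditioning: frozenset = field(default_factory=frozenset)
    selection: Optional[str] = None

    def __post_init__(self):
        if self.treatment == self.outcome:
            raise GraphInputError("treatment and outcome must differ")
        if self.treatment in self.conditioning or self.outcome in self.conditioning:
            raise GraphInputError(
                "conditioning set must not contain treatment or outcome"
            )
        object.__setattr__(self, "conditioning", frozenset(self.conditioning))


def build_dag(
    nodes: Iterable[str],
    directed: Iterable[Sequence[str]] = (),
    bidirected: Iterable[Sequence[str]] = (),
) -> CausalDAG:
    """Validate and construct a :class:`CausalDAG`.

    Raises
    ------
    GraphInputError
        Duplicate node ids or an edge endpoint that was not declared.
    GraphStructureError
        A self-loop, or a cycle in the directed part (one cycle is named).
    """
    node_list = list(nodes)
    node_set = set(node_list)
    if len(node_list) != len(node_set):
        dupes = sorted({n for n in node_list if node_list.count(n) > 1})
        raise GraphInputError(f"duplicate node ids: {dupes}")

    directed_set = set()
    for a, b in directed:
        if a not in node_set or b not in node_set:
            raise GraphInputError(f"edge ({a!r}, {b!r}) references undeclared node")
        if a == b:
            raise GraphStructureError(f"self-loop on {a!r}")
        directed_set.add((a, b))

    bidirected_set = set()
    for a, b in bidirected:
        if a not in node_set or b not in node_set:
            raise GraphInputError(
                f"bidirected edge ({a!r}, {b!r}) references undeclared node"
            )
        if a == b:
            raise GraphStructureError(f"bidirected self-loop on {a!r}")
        bidirected_set.add((min(a, b), max(a, b)))

    g = nx.DiGraph()
    g.add_nodes_from(node_set)
    g.add_edges_from(directed_set)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
        raise GraphStructureError(f"directed part contains a cycle: {path}")

    return CausalDAG(
        frozenset(node_set), frozenset(directed_set), frozenset(bidirected_set)
    )


def _adjacency(dag: CausalDAG) -> tuple:
    parents: dict = {n: set() for n in dag.nodes}
    children: dict = {n: set() for n in dag.nodes}
    for a, b in dag.directed_edges:
        parents[b].add(a)
        children[a].add(b)
    return parents, children


def _active_reachable(parents: dict, children: dict, x: str, z: frozenset) -> set:
    """Nodes reachable from ``x`` along a d-connecting path given ``z``.

    Standard active-trail reachability (Bayes-ball): traverse states
    (node, direction of entry); a collider may be passed only when it has a
    descendant in ``z``, a non-collider only when it is not in ``z``.
    Operates on adjacency maps of the latent-expanded graph.
    """
    # ancestors of z (inclusive) — a collider is unblocked iff it is here
    anc_z = set()
    stack = list(z)
    while stack:
        n = stack.pop()
        if n in anc_z:
            continue
        anc_z.add(n)
        stack.extend(parents[n])

    # state: (node, came_from_child?) — True means we entered against an arrow
    # (from a child), so we may leave to parents and children; False means we
    # entered from a parent (along an arrow), so the node acts as a collider
    # for parent-ward continuation.
    visited = set()
    reachable = set()
    agenda = [(x, True)]  # as if entered from a virtual child: free start
    while agenda:
        node, up = agenda.pop()
        if (node, up) in visited:
            continue
        visited.add((node, up))
        if node != x:
            reachable.add(node)
        if up:
            # entered from a child (or start): pass through unless conditioned
            if node not in z:
                for p in parents[node]:
                    agenda.append((p, True))
                for c in children[node]:
                    agenda.append((c, False))
        else:
            # entered from a parent: node is a collider for parent-ward moves
            if node not in z:
                for c in children[node]:
                    agenda.append((c, False))
            if node in anc_z:
                for p in parents[node]:
                    agenda.append((p, True))
    return reachable


def d_separated(dag: CausalDAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is blocked given ``z``.

    Bidirected edges are treated as hidden common parents.  Symmetric in
    ``x`` and ``y``.
    """
    zset = frozenset(z)
    for n in (x, y, *zset):
        if n not in dag.nodes:
            raise GraphInputError(f"unknown node: {n!r}")
    if x == y:
        raise GraphInputError("x and y must differ")
    if x in zset or y in zset:
        raise GraphInputError("x and y must not be in the conditioning set")
    parents, children = _adjacency(dag.latent_expansion())
    return y not in _active_reachable(parents, children, x, zset)


def is_valid_backdoor(dag: CausalDAG, query: IdentificationQuery) -> bool:
    """Back-door criterion for ``query`` on ``dag``.

    The set ``conditioning ∪ {selection}`` must (a) contain no descendant of
    the treatment and (b) d-separate treatment from outcome once all arrows
    out of the treatment are removed.
    """
    z = set(query.conditioning)
    if query.selection is not None:
        dag._require(query.selection)
        z.add(query.selection)
    for n in (query.treatment, query.outcome, *z):
        dag._require(n)

    desc = dag.descendants(query.treatment)
    if z & desc:
        return False
    trimmed = dag.remove_outgoing(query.treatment)
    return d_separated(trimmed, query.treatment, query.outcome, z)


def minimal_adjustment_sets(
    dag: CausalDAG,
    treatment: str,
    outcome: str,
    selection: Optional[str] = None,
    candidates: Optional[Iterable[str]] = None,
) -> list:
    """All inclusion-minimal valid back-door adjustment sets.

    Search is exhaustive over observed, pre-treatment nodes (non-descendants
    of the treatment) restricted to ancestors of treatment, outcome or
    selection — minimal separators cannot contain other nodes.  Returns a
    deterministically ordered list of sorted tuples (by size, then
    lexicographically); an empty list means no valid set exists.
    """
    dag._require(treatment)
    dag._require(outcome)
    if treatment == outcome:
        raise GraphInputError("treatment and outcome must differ")

    forbidden = {treatment, outcome}
    if selection is not None:
        dag._require(selection)
        forbidden.add(selection)

    expanded = dag.latent_expansion()
    anc = (
        expanded.ancestors(treatment)
        | expanded.ancestors(outcome)
        | {treatment, outcome}
    )
    if selection is not None:
        anc |= expanded.ancestors(selection) | {selection}
    pool = sorted(
        (dag.observed_nodes() & anc)
        - forbidden
        - dag.descendants(treatment)
    )
    if candidates is not None:
        pool = sorted(set(pool) & set(candidates))

    # pool members are pre-treatment, so only the separation condition of
    # the back-door criterion remains; precompute the adjacency of the
    # latent-expanded graph with the treatment's outgoing arrows removed.
    trimmed = dag.remove_outgoing(treatment).latent_expansion()
    parents, children = _adjacency(trimmed)
    base = frozenset({selection}) if selection is not None else frozenset()
    if selection is not None and selection in dag.descendants(treatment):
        return []

    def valid(zs: tuple) -> bool:
        z = base | frozenset(zs)
        return outcome not in _active_reachable(parents, children, treatment, z)

    minimal: list = []
    for size in range(len(pool) + 1):
        for combo in itertools.combinations(pool, size):
            cset = set(combo)
            if any(set(m) <= cset for m in minimal):
                continue  # proper superset of a known minimal set
            if valid(combo):
                minimal.append(combo)
    return sorted(minimal, key=lambda s: (len(s), s))


# ---------------------------------------------------------------------------
# serialization: plain-text edge list and JSON


def write_edgelist(dag: CausalDAG, path) -> None:
    """Write ``A -> B`` / ``A <-> B`` records; isolated nodes on their own line."""
    lines = []
    covered = set()
    for a, b in sorted(dag.directed_edges):
        lines.append(f"{a} -> {b}")
        covered.update((a, b))
    for a, b in sorted(dag.bidirected_edges):
        lines.append(f"{a} <-> {b}")
        covered.update((a, b))
    for n in sorted(dag.nodes - covered):
        lines.append(n)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edgelist(path) -> CausalDAG:
    nodes, directed, bidirected = set(), [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "<->" in line:
                parts = [p.strip() for p in line.split("<->")]
                if len(parts) != 2 or not all(parts):
                    raise GraphInputError(f"line {lineno}: malformed record {line!r}")
                bidirected.append(tuple(parts))
                nodes.update(parts)
            elif "->" in line:
                parts = [p.strip() for p in line.split("->")]
                if len(parts) != 2 or not all(parts):
                    raise GraphInputError(f"line {lineno}: malformed record {line!r}")
                directed.append(tuple(parts))
                nodes.update(parts)
            else:
                if " " in line:
                    raise GraphInputError(f"line {lineno}: malformed record {line!r}")
                nodes.add(line)
    return build_dag(nodes, directed, bidirected)


def dag_to_json(dag: CausalDAG, path=None) -> str:
    payload = {
        "nodes": sorted(dag.nodes),
        "directed": [list(e) for e in sorted(dag.directed_edges)],
        "bidirected": [list(e) for e in sorted(dag.bidirected_edges)],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def dag_from_json(source) -> CausalDAG:
    """Accept a JSON string or a path to a JSON file."""
    text = source
    try:
        payload = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            payload = json.load(fh)
    for key in ("nodes", "directed", "bidirected"):
        if key not in payload:
            raise GraphInputError(f"missing key {key!r} in DAG JSON")
    return build_dag(payload["nodes"], payload["directed"], payload["bidirected"])
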
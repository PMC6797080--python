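"""Identification engine: construction, d-separation, back-door queries,
minimal adjustment sets, serialization."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from juncture.causal_graph import (
    GraphInputError,
    GraphStructureError,
    IdentificationQuery,
    build_dag,
    d_separated,
    dag_from_json,
    dag_to_json,
    is_valid_backdoor,
    minimal_adjustment_sets,
    read_edgelist,
    write_edgelist,
)

from _oracles import d_separated_bruteforce, random_dag


# ---------------------------------------------------------------------------
# construction


def test_two_cycle_is_rejected_with_named_cycle():
    with pytest.raises(GraphStructureError, match="cycle"):
        build_dag(["A", "B"], [("A", "B"), ("B", "A")])


def test_self_loop_and_unknown_endpoint_rejected():
    with pytest.raises(GraphStructureError, match="self-loop"):
        build_dag(["A"], [("A", "A")])
    with pytest.raises(GraphInputError, match="undeclared"):
        build_dag(["A", "B"], [("A", "C")])
    with pytest.raises(GraphInputError, match="undeclared"):
        build_dag(["A", "B"], [], [("A", "C")])


def test_chain_dag_and_bidirected_canonicalization():
    dag = build_dag(["A", "B", "C"], [("A", "B"), ("B", "C")], [("C", "A")])
    assert dag.parents("B") == {"A"}
    assert dag.bidirected_edges == frozenset({("A", "C")})


def test_canonical_cbt_dag_has_twenty_nodes(canonical_model):
    assert len(canonical_model.dag.nodes) == 20


# ---------------------------------------------------------------------------
# d-separation


@pytest.mark.parametrize(
    "z, expected",
    [(set(), False), ({"B"}, True)],
    ids=["chain-open", "chain-blocked"],
)
def test_chain_separation(z, expected):
    dag = build_dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
    assert d_separated(dag, "A", "C", z) is expected


def test_collider_blocks_until_conditioned():
    dag = build_dag(["A", "B", "C"], [("A", "B"), ("C", "B")])
    assert d_separated(dag, "A", "C", set())
    assert not d_separated(dag, "A", "C", {"B"})


def test_collider_opened_by_descendant():
    dag = build_dag(["A", "B", "C", "D"], [("A", "B"), ("C", "B"), ("B", "D")])
    assert not d_separated(dag, "A", "C", {"D"})


def test_canonical_patient_age_separated_from_strategy(canonical_model):
    # the only V1–D2 paths run through the collider T1
    assert d_separated(canonical_model.dag, "V1", "D2", set())


def test_unknown_node_raises():
    dag = build_dag(["A", "B"], [("A", "B")])
    with pytest.raises(GraphInputError):
        d_separated(dag, "A", "Q", set())


def test_d_separation_matches_bruteforce_oracle_and_is_symmetric():
    """Exhaustive-path oracle agreement on seeded random mixed graphs."""
    rng = np.random.default_rng(7)
    for _ in range(120):
        nodes, directed, bidirected = random_dag(rng)
        dag = build_dag(nodes, directed, bidirected)
        names = sorted(nodes)
        x, y = rng.choice(names, size=2, replace=False)
        rest = [n for n in names if n not in (x, y)]
        k = int(rng.integers(0, len(rest) + 1))
        z = set(rng.choice(rest, size=k, replace=False)) if k else set()
        got = d_separated(dag, x, y, z)
        assert got == d_separated(dag, y, x, z)  # symmetry
        assert got == d_separated_bruteforce(nodes, directed, bidirected, x, y, z)


def test_d_separation_agrees_with_networkx_on_pure_dags():
    rng = np.random.default_rng(11)
    for _ in range(50):
        nodes, directed, _ = random_dag(rng, p_bidirected=0.0)
        dag = build_dag(nodes, directed)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(directed)
        names = sorted(nodes)
        x, y = rng.choice(names, size=2, replace=False)
        rest = [n for n in names if n not in (x, y)]
        z = set(rng.choice(rest, size=len(rest) // 2, replace=False)) if rest else set()
        assert d_separated(dag, x, y, z) == nx.is_d_separator(g, {x}, {y}, z)


def test_bidirected_edge_equivalent_to_explicit_latent_parent():
    """Metamorphic: A<->B behaves exactly like L->A, L->B for queries that
    do not mention the latent node."""
    rng = np.random.default_rng(23)
    for _ in range(40):
        nodes, directed, bidirected = random_dag(rng, max_nodes=6)
        if not bidirected:
            continue
        dag = build_dag(nodes, directed, bidirected)
        explicit_nodes = list(nodes)
        explicit_edges = list(directed)
        for i, (a, b) in enumerate(sorted(tuple(sorted(p)) for p in bidirected)):
            lat = f"LAT{i}"
            explicit_nodes.append(lat)
            explicit_edges += [(lat, a), (lat, b)]
        explicit = build_dag(explicit_nodes, explicit_edges)
        names = sorted(nodes)
        x, y = rng.choice(names, size=2, replace=False)
        rest = [n for n in names if n not in (x, y)]
        z = set(rng.choice(rest, size=len(rest) // 2, replace=False)) if rest else set()
        assert d_separated(dag, x, y, z) == d_separated(explicit, x, y, z)


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_separation_symmetry_property(seed):
    """d-separation is symmetric in its endpoints on arbitrary mixed graphs."""
    rng = np.random.default_rng(seed)
    nodes, directed, bidirected = random_dag(rng, max_nodes=7)
    dag = build_dag(nodes, directed, bidirected)
    names = sorted(nodes)
    x, y = rng.choice(names, size=2, replace=False)
    rest = [n for n in names if n not in (x, y)]
    z = set(rng.choice(rest, size=len(rest) // 2, replace=False)) if rest else set()
    assert d_separated(dag, x, y, z) == d_separated(dag, y, x, z)


# ---------------------------------------------------------------------------
# back-door criterion


def test_query_validation():
    with pytest.raises(GraphInputError):
        IdentificationQuery("A", "A")
    with pytest.raises(GraphInputError):
        IdentificationQuery("A", "B", frozenset({"A"}))


def test_backdoor_rejects_descendant_of_treatment():
    dag = build_dag(["A", "M", "C"], [("A", "M"), ("M", "C")])
    q = IdentificationQuery("A", "C", frozenset({"M"}))
    assert not is_valid_backdoor(dag, q)


@pytest.mark.parametrize(
    "treatment, outcome, conditioning, expected",
    [
        ("D2", "X4", {"Z1", "X2"}, True),
        ("T1", "Y2", {"V1", "V2", "Y1"}, True),
        ("T1", "Y2", set(), False),
        ("X4", "T1", {"Z1", "X2", "X5"}, True),
        ("X4", "T1", {"Z1", "X2"}, False),
    ],
)
def test_canonical_backdoor_queries(
    canonical_model, treatment, outcome, conditioning, expected
):
    q = IdentificationQuery(treatment, outcome, frozenset(conditioning), "D1")
    assert is_valid_backdoor(canonical_model.dag, q) is expected


# ---------------------------------------------------------------------------
# minimal adjustment sets


def test_chain_needs_no_adjustment():
    dag = build_dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
    assert minimal_adjustment_sets(dag, "A", "C") == [()]


def test_single_confounder():
    dag = build_dag(["U", "A", "C"], [("U", "A"), ("U", "C"), ("A", "C")])
    assert minimal_adjustment_sets(dag, "A", "C") == [("U",)]


def test_unblockable_latent_confounding_yields_empty_collection():
    dag = build_dag(["A", "C"], [("A", "C")], [("A", "C")])
    assert minimal_adjustment_sets(dag, "A", "C") == []


def test_canonical_feasibility_effect_minimal_sets(canonical_model):
    sets = minimal_adjustment_sets(canonical_model.dag, "X4", "T1", selection="D1")
    # the named set {Z1, X2, X5} is among the minimal sets
    assert ("X2", "X5", "Z1") in sets
    # deterministic ordering: by size then lexicographic
    assert sets == sorted(sets, key=lambda s: (len(s), s))


def test_minimal_sets_are_valid_and_inclusion_minimal(canonical_model):
    dag = canonical_model.dag
    for treatment, outcome in [("X4", "T1"), ("D2", "X4"), ("T1", "Y2")]:
        sets = minimal_adjustment_sets(dag, treatment, outcome, selection="D1")
        assert sets
        for s in sets:
            q = IdentificationQuery(treatment, outcome, frozenset(s), "D1")
            assert is_valid_backdoor(dag, q)
            for drop in s:
                sub = frozenset(set(s) - {drop})
                q2 = IdentificationQuery(treatment, outcome, sub, "D1")
                assert not is_valid_backdoor(dag, q2)


# ---------------------------------------------------------------------------
# serialization


def test_edgelist_round_trip(tmp_path, canonical_model):
    path = tmp_path / "dag.txt"
    write_edgelist(canonical_model.dag, path)
    assert read_edgelist(path) == canonical_model.dag


def test_edgelist_round_trip_with_isolated_node(tmp_path):
    dag = build_dag(["A", "B", "Solo"], [("A", "B")], [("A", "B")])
    path = tmp_path / "dag.txt"
    write_edgelist(dag, path)
    assert read_edgelist(path) == dag


def test_edgelist_malformed_line(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("A -> B\nA -> \n")
    with pytest.raises(GraphInputError, match="line 2"):
        read_edgelist(path)


def test_json_round_trip(tmp_path, canonical_model):
    path = tmp_path / "dag.json"
    dag_to_json(canonical_model.dag, path)
    assert dag_from_json(path) == canonical_model.dag
    text = dag_to_json(canonical_model.dag)
    assert dag_from_json(text) == canonical_model.dag
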
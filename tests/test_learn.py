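import numpy as np
import pandas as pd
import pytest

from metabonet import (
    ConstraintSet,
    Dag,
    SearchParams,
    average_network,
    bic_score,
    bootstrap_arc_strengths,
    layering_constraints,
    sample_from_bn,
    tabu_search,
)
from metabonet.graphs import ConstraintError, CycleError, is_acyclic
from metabonet.infer import BnModel
from metabonet.learn import ArcStrengthTable, DiscreteTable, SchemaError
from oracles import enumerate_dags, naive_bic, random_discrete_frame


# -- graphs ----------------------------------------------------------------

def test_acyclicity_cases():
    assert is_acyclic(("a", "b", "c"), {("a", "b"), ("b", "c")})
    assert not is_acyclic(("a", "b"), {("a", "b"), ("b", "a")})
    assert is_acyclic((), set())
    with pytest.raises(CycleError):
        Dag(("a", "b"), {("a", "b"), ("b", "a")})


def test_dag_rejects_self_loops_and_unknown_endpoints():
    with pytest.raises(ValueError):
        Dag(("a",), {("a", "a")})
    with pytest.raises(ValueError):
        Dag(("a",), {("a", "b")})


def test_constraints_must_be_consistent():
    with pytest.raises(ConstraintError):
        ConstraintSet(blacklist={("a", "b")}, whitelist={("a", "b")})
    with pytest.raises(ConstraintError):
        ConstraintSet(whitelist={("a", "b"), ("b", "a")})


def test_layering_constraints_contents():
    roles = {"hyperuricemia": "outcome", "mets": "exposure", "bmi_level": "exposure",
             "sex": "demographic"}
    roles.update({f"c{i}": "covariate" for i in range(10)})
    cons = layering_constraints(roles)
    others = [v for v in roles if v != "hyperuricemia"]
    for v in others:
        assert ("hyperuricemia", v) in cons.blacklist
    assert ("mets", "bmi_level") in cons.blacklist
    assert ("bmi_level", "mets") in cons.blacklist
    assert ("mets", "hyperuricemia") not in cons.blacklist
    assert ("sex", "hyperuricemia") not in cons.blacklist
    assert cons.whitelist == frozenset()


def test_layering_requires_one_outcome():
    with pytest.raises(ValueError):
        layering_constraints({"a": "covariate"})


# -- BIC -------------------------------------------------------------------

def test_bic_single_binary_node_hand_value():
    df = pd.DataFrame({"x": [0, 0, 0, 0, 1, 1, 1, 1]})
    total, per = bic_score(Dag(("x",)), df)
    expected = 8 * np.log(0.5) - np.log(8) / 2
    assert total == pytest.approx(expected, abs=1e-12)
    assert per["x"] == pytest.approx(expected, abs=1e-12)


def test_bic_irrelevant_parent_costs_exactly_the_penalty():
    """If per-configuration child frequencies are identical, adding the
    parent changes the score by exactly -(ln N)/2 * delta(q (r-1))."""
    # child balanced within each parent block
    df = pd.DataFrame({"p": [0] * 4 + [1] * 4, "x": [0, 0, 1, 1] * 2})
    base, _ = bic_score(Dag(("p", "x")), df)
    with_arc, _ = bic_score(Dag(("p", "x"), {("p", "x")}), df)
    assert with_arc - base == pytest.approx(-np.log(8) / 2, abs=1e-12)


def test_bic_matches_naive_recount_on_random_dags(rng):
    """Cache-correctness oracle: decomposed scores equal a from-scratch
    pandas recount on random 4-node graphs."""
    for _ in range(15):
        df = random_discrete_frame(rng, n_nodes=4, n_rows=400)
        dags = enumerate_dags(tuple(df.columns)[:3])  # vary structure cheaply
        dag = dags[int(rng.integers(len(dags)))]
        sub = df[list(dag.nodes)]
        total, _ = bic_score(dag, sub)
        assert total == pytest.approx(naive_bic(dag, sub), abs=1e-9)


def test_bic_rejects_undeclared_levels():
    df = pd.DataFrame({"x": [0, 1, 2]})
    with pytest.raises(SchemaError):
        bic_score(Dag(("x",)), DiscreteTable.from_dataframe(df, levels={"x": [0, 1]}))


def test_discrete_table_resample_preserves_mass(rng):
    df = random_discrete_frame(rng, 3, 100)
    t = DiscreteTable.from_dataframe(df)
    b = t.resample(rng)
    assert b.n == t.n
    assert b.codes.shape[1] == t.codes.shape[1]


# -- tabu search -----------------------------------------------------------

def _chain_data(n=50_000, seed=0):
    dag = Dag(("A", "B", "C"), {("A", "B"), ("B", "C")})
    strong = np.array([[0.9, 0.1], [0.1, 0.9]])
    bn = BnModel(dag=dag, levels={v: [0, 1] for v in "ABC"},
                 cpts={"A": np.array([0.5, 0.5]), "B": strong, "C": strong})
    return sample_from_bn(bn, n, seed)


def test_tabu_attains_exhaustive_maximum_on_chain():
    data = _chain_data()
    best = max(bic_score(d, data)[0] for d in enumerate_dags(("A", "B", "C")))
    got = bic_score(tabu_search(data), data)[0]
    assert got == pytest.approx(best, abs=1e-9)


def test_tabu_leaves_independent_variables_unconnected(rng):
    df = pd.DataFrame({c: rng.integers(0, 2, 10_000) for c in "ABC"})
    assert tabu_search(df).arcs == frozenset()


def test_tabu_respects_blacklist_and_whitelist():
    data = _chain_data(n=20_000, seed=4)
    cons = ConstraintSet(blacklist={("A", "B"), ("B", "A")})
    for seed in range(20):
        dag = tabu_search(data, cons, SearchParams(seed=seed, restarts=2))
        assert ("A", "B") not in dag.arcs and ("B", "A") not in dag.arcs
    forced = ConstraintSet(whitelist={("C", "A")})
    dag = tabu_search(data, forced)
    assert ("C", "A") in dag.arcs


def test_tabu_output_always_acyclic_and_deterministic(rng):
    df = random_discrete_frame(rng, 4, 800)
    a, b = tabu_search(df), tabu_search(df)
    assert a.arcs == b.arcs  # deterministic move ordering
    assert is_acyclic(a.nodes, a.arcs)


def test_enumerate_dags_counts_25_on_three_nodes():
    assert len(enumerate_dags(("A", "B", "C"))) == 25


# -- bootstrap and averaging ----------------------------------------------

def test_bootstrap_constant_learner_gives_unit_strength():
    df = pd.DataFrame({"A": [0, 1] * 20, "B": [0, 1] * 20})
    fixed = Dag(("A", "B"), {("A", "B")})
    st = bootstrap_arc_strengths(df, R=5, learner=lambda t: fixed)
    assert st.strength("A", "B") == 1.0
    assert st.direction("A", "B") == 1.0
    assert st.strength("B", "A") == 1.0  # presence ignores orientation
    assert st.direction("B", "A") == 0.0


def test_bootstrap_strength_granularity():
    data = _chain_data(n=2000, seed=9)
    st = bootstrap_arc_strengths(data, R=7, params=SearchParams(seed=2))
    vals = st.frame["strength"].to_numpy() * 7
    assert np.allclose(vals, np.round(vals))


def test_bootstrap_reproducible_given_seed():
    data = _chain_data(n=2000, seed=9)
    a = bootstrap_arc_strengths(data, R=10, params=SearchParams(seed=3)).frame
    b = bootstrap_arc_strengths(data, R=10, params=SearchParams(seed=3)).frame
    assert a.equals(b)


def _strength_table(rows, nodes):
    frame = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
    return ArcStrengthTable(frame=frame, R=100, nodes=nodes)


def test_average_network_threshold_filter_and_orientation():
    st = _strength_table(
        [("A", "B", 0.9, 0.8), ("B", "A", 0.9, 0.2),
         ("B", "C", 0.6, 0.5), ("C", "B", 0.6, 0.5)],
        ("A", "B", "C"),
    )
    dag = average_network(st, 0.85)
    assert dag.arcs == frozenset({("A", "B")})


def test_average_network_monotone_in_threshold():
    st = _strength_table(
        [("A", "B", 0.9, 1.0), ("B", "A", 0.9, 0.0),
         ("B", "C", 0.6, 1.0), ("C", "B", 0.6, 0.0)],
        ("A", "B", "C"),
    )
    assert len(average_network(st, 0.5).arcs) >= len(average_network(st, 0.85).arcs)


def test_average_network_drops_weakest_arc_on_cycle():
    st = _strength_table(
        [("A", "B", 0.9, 1.0), ("B", "A", 0.9, 0.0),
         ("B", "C", 0.8, 1.0), ("C", "B", 0.8, 0.0),
         ("C", "A", 0.7, 1.0), ("A", "C", 0.7, 0.0)],
        ("A", "B", "C"),
    )
    dag = average_network(st, 0.5)
    assert dag.arcs == frozenset({("A", "B"), ("B", "C")})  # weakest (C->A) dropped


def test_average_network_direction_tie_breaks_to_smaller_source():
    st = _strength_table(
        [("A", "B", 0.9, 0.5), ("B", "A", 0.9, 0.5)], ("A", "B")
    )
    assert average_network(st, 0.5).arcs == frozenset({("A", "B")})
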
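import numpy as np
import pandas as pd
import pytest

from metabonet import (
    BnModel,
    Dag,
    exact_query,
    fit_cpts,
    joint_probability,
    lw_query,
    reasoning_table,
    sample_from_bn,
)
from metabonet.infer import InconsistentEvidenceError
from metabonet.reference import (
    REASONING_SCENARIOS,
    reasoning_reference_network,
    recovery_reference_network,
)
from oracles import brute_force_query, random_bn


def _chain(pa=0.3, pb_given=((0.9, 0.1), (0.5, 0.5))):
    dag = Dag(("A", "B"), {("A", "B")})
    return BnModel(
        dag=dag, levels={"A": [0, 1], "B": [0, 1]},
        cpts={"A": np.array([1 - pa, pa]), "B": np.array(pb_given)},
    )


# -- CPT estimation --------------------------------------------------------

def test_fit_cpts_mle_and_laplace():
    df = pd.DataFrame({"x": [0, 0, 0, 1]})
    dag = Dag(("x",))
    mle = fit_cpts(dag, df)
    assert np.allclose(mle.cpts["x"], [0.75, 0.25])
    assert mle.smoothing == 0.0
    lap = fit_cpts(dag, df, alpha=1.0)
    assert np.allclose(lap.cpts["x"], [4 / 6, 2 / 6])


def test_fit_cpts_unseen_parent_config_uniform_with_warning():
    df = pd.DataFrame({"p": [0, 0, 0], "x": [0, 1, 0]})
    dag = Dag(("p", "x"), {("p", "x")})
    with pytest.warns(UserWarning, match="unobserved parent configuration"):
        bn = fit_cpts(dag, df, levels={"p": [0, 1], "x": [0, 1]})
    assert np.allclose(bn.cpts["x"][1], [0.5, 0.5])


def test_cpt_rows_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        BnModel(dag=Dag(("x",)), levels={"x": [0, 1]}, cpts={"x": np.array([0.5, 0.4])})


def test_cpt_shape_validated():
    with pytest.raises(ValueError, match="shape"):
        BnModel(dag=Dag(("x",)), levels={"x": [0, 1, 2]}, cpts={"x": np.array([0.5, 0.5])})


# -- joint probability -----------------------------------------------------

def test_joint_probability_two_factor_product():
    bn = _chain(pa=0.3, pb_given=((0.9, 0.1), (0.5, 0.5)))
    assert joint_probability(bn, {"A": 1, "B": 1}) == pytest.approx(0.15)


def test_joint_probability_normalises(rng):
    from itertools import product

    for _ in range(5):
        bn = random_bn(rng, n_nodes=4)
        total = sum(
            joint_probability(bn, dict(zip(bn.dag.nodes, combo)))
            for combo in product(*(bn.levels[v] for v in bn.dag.nodes))
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_joint_probability_zero_factor_annihilates():
    bn = _chain(pa=0.0)
    assert joint_probability(bn, {"A": 1, "B": 0}) == 0.0


# -- exact queries ---------------------------------------------------------

def test_exact_query_direct_conditioning_returns_cpt_row():
    bn = _chain()
    res = exact_query(bn, "B", {"A": 1})
    assert res[0] == pytest.approx(0.5) and res[1] == pytest.approx(0.5)


def test_exact_query_marginal_by_total_probability():
    bn = _chain(pa=0.3)
    res = exact_query(bn, "B")
    assert res[1] == pytest.approx(0.5 * 0.3 + 0.1 * 0.7)


def test_exact_query_matches_brute_force_on_collider():
    dag = Dag(("A", "B", "C", "D"), {("A", "C"), ("B", "C"), ("C", "D")})
    rng = np.random.default_rng(7)
    levels = {v: [0, 1] for v in "ABCD"}
    cpts = {
        "A": np.array([0.6, 0.4]),
        "B": np.array([0.3, 0.7]),
        "C": rng.dirichlet([1, 1], size=(2, 2)),
        "D": rng.dirichlet([1, 1], size=2),
    }
    bn = BnModel(dag=dag, levels=levels, cpts=cpts)
    for evidence in ({"A": 1}, {"A": 0, "D": 1}, {"B": 1, "D": 0}, {}):
        got = exact_query(bn, "C", evidence).distribution
        want = brute_force_query(bn, "C", evidence)
        for lv in (0, 1):
            assert got[lv] == pytest.approx(want[lv], abs=1e-12)


def test_exact_query_matches_brute_force_on_random_networks(rng):
    for _ in range(5):
        bn = random_bn(rng, n_nodes=5)
        target = bn.dag.nodes[-1]
        ev_node = bn.dag.nodes[0]
        evidence = {ev_node: bn.levels[ev_node][0]}
        try:
            got = exact_query(bn, target, evidence).distribution
        except InconsistentEvidenceError:
            continue
        want = brute_force_query(bn, target, evidence)
        for lv in bn.levels[target]:
            assert got[lv] == pytest.approx(want[lv], abs=1e-12)


def test_exact_query_distribution_sums_to_one(rng):
    for _ in range(5):
        bn = random_bn(rng, n_nodes=4)
        res = exact_query(bn, bn.dag.nodes[0])
        assert sum(res.distribution.values()) == pytest.approx(1.0, abs=1e-9)


def test_exact_query_inconsistent_evidence_raises():
    bn = _chain(pa=0.0)  # A=1 impossible
    with pytest.raises(InconsistentEvidenceError):
        exact_query(bn, "B", {"A": 1})


def test_exact_query_target_cannot_be_evidence():
    with pytest.raises(ValueError):
        exact_query(_chain(), "B", {"B": 1})


# -- likelihood weighting --------------------------------------------------

def test_lw_no_evidence_equals_forward_sampling_frequency():
    bn = _chain(pa=0.3)
    res = lw_query(bn, "A", {}, n_samples=100_000, seed=3)
    assert res[1] == pytest.approx(0.3, abs=4 * res.mc_error[1])


def test_lw_query_within_three_errors_of_exact():
    bn = reasoning_reference_network()
    evidence = {"bmi_group": "obese", "components": 2}
    exact = exact_query(bn, "hyperuricemia", evidence)
    lw = lw_query(bn, "hyperuricemia", evidence, n_samples=200_000, seed=17)
    assert abs(lw[1] - exact[1]) < 3 * lw.mc_error[1] + 1e-12


def test_lw_query_deterministic_given_seed():
    bn = _chain()
    a = lw_query(bn, "B", {"A": 1}, 5000, seed=4)
    b = lw_query(bn, "B", {"A": 1}, 5000, seed=4)
    assert a.distribution == b.distribution


def test_lw_query_impossible_evidence_raises():
    bn = _chain(pa=0.0)
    with pytest.raises(InconsistentEvidenceError):
        lw_query(bn, "B", {"A": 1}, 1000, seed=0)


# -- round trip and reasoning ---------------------------------------------

def test_cpt_round_trip_recovery_within_one_percent():
    """Refitting CPTs on 100,000 forward samples recovers every entry of a
    known network within 0.01 (every parent configuration well occupied)."""
    dag3 = Dag(("A", "B", "C"), {("A", "B"), ("B", "C")})
    bn = BnModel(
        dag=dag3, levels={v: [0, 1] for v in "ABC"},
        cpts={"A": np.array([0.4, 0.6]),
              "B": np.array([[0.8, 0.2], [0.3, 0.7]]),
              "C": np.array([[0.65, 0.35], [0.25, 0.75]])},
    )
    data = sample_from_bn(bn, 100_000, seed=19)
    refit = fit_cpts(bn.dag, data, levels=bn.levels)
    for v in bn.dag.nodes:
        assert np.max(np.abs(refit.cpts[v] - bn.cpts[v])) < 0.01, v


def test_forward_samples_match_joint_probabilities():
    """Empirical joint cell frequencies converge to the factorised joint."""
    from itertools import product

    bn = _chain(pa=0.3)
    dag3 = Dag(("A", "B", "C"), {("A", "B"), ("B", "C")})
    strong = np.array([[0.8, 0.2], [0.3, 0.7]])
    bn3 = BnModel(dag=dag3, levels={v: [0, 1] for v in "ABC"},
                  cpts={"A": np.array([0.4, 0.6]), "B": strong, "C": strong})
    df = sample_from_bn(bn3, 100_000, seed=23)
    joined = df.value_counts(normalize=True)
    for combo in product([0, 1], repeat=3):
        emp = joined.get(combo, 0.0)
        want = joint_probability(bn3, dict(zip("ABC", combo)))
        assert abs(emp - want) < 0.01


def test_reasoning_table_rows_and_monotonicity():
    bn = reasoning_reference_network()
    tab = reasoning_table(bn, REASONING_SCENARIOS, "hyperuricemia", 1)
    assert len(tab) == len(REASONING_SCENARIOS)
    # obese rows with growing component count: monotone increasing risk
    obese = tab.iloc[1:5]["probability"].to_numpy()
    assert np.all(np.diff(obese) > 0)


def test_reasoning_table_duplicate_scenarios_identical():
    bn = reasoning_reference_network()
    sc = {"bmi_group": "obese", "components": 2}
    tab = reasoning_table(bn, [sc, sc])
    assert tab.iloc[0]["probability"] == tab.iloc[1]["probability"]


def test_reasoning_table_empty_evidence_is_marginal():
    bn = reasoning_reference_network()
    tab = reasoning_table(bn, [{}])
    assert tab.iloc[0]["probability"] == pytest.approx(
        exact_query(bn, "hyperuricemia")[1]
    )


def test_bnmodel_json_round_trip(tmp_path):
    bn = reasoning_reference_network()
    path = tmp_path / "bn.json"
    bn.to_json(path)
    clone = BnModel.from_json(path)
    assert clone.dag == bn.dag
    assert clone.levels == bn.levels
    for v in bn.dag.nodes:
        assert np.allclose(clone.cpts[v], bn.cpts[v])
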
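import warnings

import numpy as np
import pandas as pd
import pytest

from metabonet import (
    AssociationModel,
    GeneratorSpec,
    derive_phenotypes,
    fit_logistic,
    odds_ratio_table,
    prevalence_ci,
    run_association_models,
    sample_cohort,
    stepwise_select,
)
from metabonet.epi import (
    NotConvergedError,
    RankDeficientError,
    describe_cohort,
    prevalence_by_phenotype,
)


# -- prevalence -----------------------------------------------------------

def test_wilson_zero_events():
    c = prevalence_ci(0, 10)
    assert c.p_hat == 0.0 and c.ci_low == 0.0 and 0 < c.ci_high < 1


def test_wilson_matches_closed_form_example():
    # 12 of 142: 8.5% (4.9-14.2%) by the Wilson closed form
    c = prevalence_ci(12, 142)
    assert round(100 * c.p_hat, 1) == 8.5
    assert round(100 * c.ci_low, 1) == 4.9
    assert round(100 * c.ci_high, 1) == 14.2


def test_wilson_symmetric_at_half():
    c = prevalence_ci(5, 10)
    assert (c.p_hat - c.ci_low) == pytest.approx(c.ci_high - c.p_hat, abs=1e-12)


def test_interval_always_inside_unit_interval():
    for k in range(0, 21):
        for method in ("wilson", "clopper-pearson"):
            c = prevalence_ci(k, 20, method=method)
            assert 0 <= c.ci_low <= c.p_hat <= c.ci_high <= 1


def test_prevalence_rejects_k_above_n():
    with pytest.raises(ValueError):
        prevalence_ci(11, 10)


def test_prevalence_by_phenotype_shape(small_phenotyped):
    tab = prevalence_by_phenotype(small_phenotyped)
    assert len(tab) == 12  # 6 phenotypes x 2 sexes
    occupied = tab.dropna()
    assert ((occupied["ci_low_pct"] <= occupied["prevalence_pct"])
            & (occupied["prevalence_pct"] <= occupied["ci_high_pct"])).all()


# -- descriptives ---------------------------------------------------------

def test_describe_identical_groups_null_t():
    half = pd.DataFrame({"age": np.linspace(20, 70, 50), "smoker": [0, 1] * 25})
    df = pd.concat([half.assign(sex="male"), half.assign(sex="female")], ignore_index=True)
    out = describe_cohort(df).set_index("variable")
    assert out.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc["age", "p_value"] == pytest.approx(1.0)


def test_describe_chi_square_uncorrected_hand_value():
    # 2x2 counts (30,70 / 50,50): sum (O-E)^2/E = 8.3333
    g = ["male"] * 100 + ["female"] * 100
    x = [1] * 30 + [0] * 70 + [1] * 50 + [0] * 50
    df = pd.DataFrame({"sex": g, "smoker": x})
    out = describe_cohort(df).set_index("variable")
    assert out.loc["smoker", "statistic"] == pytest.approx(25 / 3, rel=1e-9)


def test_describe_single_group_errors():
    df = pd.DataFrame({"sex": ["male"] * 5, "age": range(5)})
    with pytest.raises(ValueError):
        describe_cohort(df)


def test_describe_zero_variance_warns():
    df = pd.DataFrame({"sex": ["male"] * 5 + ["female"] * 5, "age": [50.0] * 10})
    with pytest.warns(UserWarning, match="zero variance"):
        out = describe_cohort(df).set_index("variable")
    assert np.isnan(out.loc["age", "statistic"])


# -- logistic fits --------------------------------------------------------

def test_logistic_saturated_fit_equals_cross_product_ratio():
    X = pd.DataFrame({"const": 1.0, "x": [1.0] * 100 + [0.0] * 100})
    y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
    fit = fit_logistic(X, y)
    assert fit.converged
    assert fit.params["x"] == pytest.approx(np.log(2.25), abs=1e-6)


def test_logistic_intercept_only_closed_form():
    X = pd.DataFrame({"const": np.ones(200)})
    y = np.r_[np.ones(50), np.zeros(150)]
    fit = fit_logistic(X, y)
    assert fit.params["const"] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)


def test_logistic_rank_deficiency_names_terms():
    X = pd.DataFrame({"const": np.ones(50), "x": np.arange(50.0)})
    X["x_copy"] = X["x"]
    with pytest.raises(RankDeficientError, match="x"):
        fit_logistic(X, np.r_[np.ones(25), np.zeros(25)])


def test_logistic_separation_flagged_not_converged():
    x = np.r_[np.ones(20), np.zeros(20)]
    X = pd.DataFrame({"const": 1.0, "x": x})
    fit = fit_logistic(X, x)  # outcome identical to predictor: perfect separation
    assert not fit.converged
    with pytest.raises(NotConvergedError):
        odds_ratio_table(fit)


def test_odds_ratio_wald_interval_closed_form():
    X = pd.DataFrame({"const": 1.0, "x": [1.0] * 100 + [0.0] * 100})
    y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
    tab = odds_ratio_table(fit_logistic(X, y), ["x"]).iloc[0]
    b, se = np.log(2.25), np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
    assert tab["or"] == pytest.approx(2.25, rel=1e-6)
    assert tab["ci_low"] == pytest.approx(np.exp(b - 1.959964 * se), rel=1e-4)
    assert tab["ci_high"] == pytest.approx(np.exp(b + 1.959964 * se), rel=1e-4)


def test_published_or_interval_arithmetic():
    # a coefficient of 0.668 with SE 0.3315 prints as OR 1.95 (1.02-3.74)
    b, se = 0.668, 0.3315
    assert np.exp(b) == pytest.approx(1.95, abs=0.005)
    assert np.exp(b - 1.959964 * se) == pytest.approx(1.02, abs=0.005)
    assert np.exp(b + 1.959964 * se) == pytest.approx(3.74, abs=0.006)


def test_or_point_estimates_invariant_to_covariate_scaling():
    rng = np.random.default_rng(3)
    n = 2000
    age = rng.uniform(20, 80, n)
    x = rng.integers(0, 2, n).astype(float)
    eta = -2.0 + 0.7 * x + 0.02 * age
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X1 = pd.DataFrame({"const": 1.0, "x": x, "age": age})
    X2 = pd.DataFrame({"const": 1.0, "x": x, "age": (age - 50.0) / 10.0})
    or1 = odds_ratio_table(fit_logistic(X1, y), ["x"]).iloc[0]["or"]
    or2 = odds_ratio_table(fit_logistic(X2, y), ["x"]).iloc[0]["or"]
    assert or1 == pytest.approx(or2, rel=1e-8)


# -- association models ---------------------------------------------------

def test_association_table_shape_and_reference_rows(small_phenotyped):
    tab = run_association_models(small_phenotyped)
    assert len(tab) == 36  # 6 phenotypes x 3 strata x 2 models
    ref = tab[tab["reference"]]
    assert (ref["phenotype"] == "MHNW").all()
    assert (ref["or"] == 1.0).all()
    assert len(ref) == 6


def test_association_results_summary(small_phenotyped):
    res = AssociationModel(small_phenotyped).fit()
    text = res.summary()
    assert "women" in text and "MHO" in text and "1 (reference)" in text


def test_empty_phenotype_cell_warns_and_yields_undefined_or(small_phenotyped):
    df = small_phenotyped[small_phenotyped["phenotype"] != "MHO"]
    with pytest.warns(UserWarning, match="MHO"):
        tab = run_association_models(df)
    mho = tab[tab["phenotype"] == "MHO"]
    assert mho["or"].isna().all()


def test_men_only_stratum_without_sex_term(small_phenotyped):
    """Sex-stratified fits drop the sex term: a men-only cohort must fit
    without error and report no women's estimates."""
    men = small_phenotyped[small_phenotyped["sex"] == "male"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = run_association_models(men)
    women = tab[(tab["stratum"] == "women") & (~tab["reference"])]
    assert women["or"].isna().all()
    assert tab[(tab["stratum"] == "men") & (tab["model"] == 1)]["or"].notna().sum() >= 4


# -- stepwise selection ----------------------------------------------------

def _stepwise_frame(seed=0, n=2000):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    noise1 = rng.normal(size=n)
    noise2 = rng.integers(0, 2, n).astype(float)
    eta = -1.0 + 1.5 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = pd.DataFrame({"const": 1.0, "x": x, "noise1": noise1, "noise2": noise2})
    return X, y


def test_stepwise_retains_generating_term_drops_noise():
    X, y = _stepwise_frame()
    kept, fit = stepwise_select(X, y, ["x", "noise1", "noise2"])
    assert "x" in kept
    assert fit.converged


def test_stepwise_deterministic_given_order():
    X, y = _stepwise_frame(seed=5)
    a = stepwise_select(X, y, ["x", "noise1", "noise2"])[0]
    b = stepwise_select(X, y, ["x", "noise1", "noise2"])[0]
    assert a == b


def test_stepwise_blocks_move_together():
    rng = np.random.default_rng(11)
    n = 3000
    g = rng.integers(0, 3, n)
    d1, d2 = (g == 1).astype(float), (g == 2).astype(float)
    eta = -1.0 + 1.0 * d1 + 1.5 * d2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = pd.DataFrame({"const": 1.0, "ph_1": d1, "ph_2": d2,
                      "noise": rng.normal(size=n)})
    kept, _ = stepwise_select(X, y, ["ph_1", "ph_2", "noise"],
                              blocks={"phenotype": ["ph_1", "ph_2"]})
    assert {"ph_1", "ph_2"} <= set(kept)  # the block survives as a unit
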
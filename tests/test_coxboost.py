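"""Cox boosting: loss oracles, tree behavior, ensemble invariants, fusion."""

import numpy as np
import pandas as pd
import pytest

from adprog.coxboost import (
    BoostedCoxEnsemble,
    cox_negative_gradient,
    cox_partial_loglik,
    fit_gbm,
    fit_regression_tree,
    predict_risk,
    two_step_fusion,
    variable_importance,
)
from adprog.coxboost.tree import Binner, Node, RegressionTree
from adprog.evaluation import harrell_c


def _weibull_outcomes(rng, lp, scale=60.0, shape=1.5, horizon=96.0):
    t = scale * (-np.log(rng.random(len(lp))) * np.exp(-lp)) ** (1 / shape)
    d = (t <= horizon).astype(int)
    return np.minimum(t, horizon), d


# ---------------------------------------------------------------- loss
def test_partial_loglik_hand_example():
    assert cox_partial_loglik([0, 0, 0], [1, 2, 3], [1, 1, 1]) == pytest.approx(-np.log(6))


def test_partial_loglik_shift_invariance():
    rng = np.random.default_rng(0)
    f = rng.standard_normal(15)
    t = rng.exponential(5, 15)
    d = np.r_[np.ones(8), np.zeros(7)].astype(int)
    a = cox_partial_loglik(f, t, d)
    b = cox_partial_loglik(f + 10, t, d)
    assert a == pytest.approx(b, abs=1e-10)


def test_partial_loglik_single_event_is_zero():
    assert cox_partial_loglik([1.7], [5.0], [1]) == pytest.approx(0.0)


def test_partial_loglik_requires_events():
    with pytest.raises(ValueError, match="event"):
        cox_partial_loglik([0.0, 1.0], [1.0, 2.0], [0, 0])


def test_negative_gradient_hand_example():
    r = cox_negative_gradient([0, 0, 0], [1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(r, [2 / 3, 1 / 6, -5 / 6])


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = 20
        f = rng.standard_normal(n)
        t = rng.exponential(5, n)
        d = rng.integers(0, 2, n)
        if d.sum() == 0:
            d[0] = 1
        g = cox_negative_gradient(f, t, d)
        assert abs(g.sum()) < 1e-9
        h = 1e-5
        for i in rng.choice(n, 5, replace=False):
            e = np.zeros(n)
            e[i] = h
            fd = (cox_partial_loglik(f + e, t, d) - cox_partial_loglik(f - e, t, d)) / (2 * h)
            assert abs(g[i] - fd) < 1e-6


# ---------------------------------------------------------------- trees
def test_perfect_binary_split_gives_depth_one_tree():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"a": np.tile([0.0, 1.0], 20), "b": rng.standard_normal(40)})
    r = np.where(X["a"] == 0, -2.0, 2.0)
    tree, binner = fit_regression_tree(X, r, min_leaf=5)
    assert tree.depth == 1
    assert tree.nodes[0].feature == 0
    pred = tree.predict_codes(binner.transform(X))
    np.testing.assert_allclose(pred, r)  # zero within-leaf variance


def test_stumps_cannot_express_xor_interaction():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 2, 200)
    b = rng.integers(0, 2, 200)
    X = pd.DataFrame({"a": a.astype(float), "b": b.astype(float)})
    r = np.where(a ^ b, 1.0, -1.0)

    def sse(depth):
        tree, binner = fit_regression_tree(X, r, max_depth=depth, min_leaf=5)
        pred = tree.predict_codes(binner.transform(X))
        return ((r - pred) ** 2).sum()

    assert sse(2) <= sse(1) - 1.0  # depth 2 captures the interaction


def test_surrogate_duplicate_column_routes_missing_like_observed():
    # 'a' drives the residual and is 30% missing; 'dup' is an exact copy that
    # is itself missing on a disjoint (larger) row set, so 'a' wins the primary
    # split and 'dup' becomes its surrogate wherever 'a' is unobserved.
    rng = np.random.default_rng(3)
    a = rng.standard_normal(200)
    r = np.where(a > 0, 1.0, -1.0)
    miss_a = rng.choice(200, 60, replace=False)
    rest = np.setdiff1d(np.arange(200), miss_a)
    miss_dup = rng.choice(rest, 80, replace=False)
    a_missing = a.copy()
    a_missing[miss_a] = np.nan
    dup_missing = a.copy()
    dup_missing[miss_dup] = np.nan
    X_miss = pd.DataFrame({"a": a_missing, "dup": dup_missing})
    tree, binner = fit_regression_tree(X_miss, r, max_depth=1, min_leaf=5)
    node = tree.nodes[0]
    assert node.feature == 0
    assert node.surrogate is not None and node.surrogate[0] == 1
    pred_miss = tree.predict_codes(binner.transform(X_miss))
    pred_full = tree.predict_codes(binner.transform(pd.DataFrame({"a": a, "dup": a})))
    np.testing.assert_allclose(pred_miss, pred_full)


def test_constant_residuals_give_single_leaf():
    X = pd.DataFrame({"a": np.arange(30.0)})
    tree, _ = fit_regression_tree(X, np.ones(30))
    assert len(tree.nodes) == 1 and tree.nodes[0].feature == -1


def test_categorical_split_selects_level_subset():
    rng = np.random.default_rng(4)
    cats = rng.choice(list("wxyz"), 400)
    X = pd.DataFrame({"c": pd.Categorical(cats)})
    r = np.where(np.isin(cats, ["w", "y"]), 1.0, -1.0)
    tree, binner = fit_regression_tree(X, r, max_depth=1, min_leaf=5)
    pred = tree.predict_codes(binner.transform(X))
    assert ((pred > 0) == (r > 0)).all()


# ---------------------------------------------------------------- ensembles
def test_planted_feature_has_largest_influence():
    rng = np.random.default_rng(5)
    n, p = 500, 20
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    t, d = _weibull_outcomes(rng, 2.0 * X["x0"].to_numpy())
    ens = fit_gbm(X, t, d, nu=0.1, n_max=80, inner_folds=3, seed=1)
    imp = variable_importance(ens)
    assert max(imp, key=imp.get) == "x0"


def test_pure_noise_features_give_chance_level():
    rng = np.random.default_rng(6)
    n, p = 300, 15
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    t, d = _weibull_outcomes(rng, np.zeros(n))
    with pytest.warns() if False else np.errstate():
        ens = fit_gbm(X.iloc[:200], t[:200], d[:200], nu=0.1, n_max=60,
                      inner_folds=3, seed=2)
    c = harrell_c(ens.predict(X.iloc[200:]), t[200:], d[200:])
    assert c == pytest.approx(0.5, abs=0.07)
    assert ens.n_trees <= 30  # inner CV stops early without signal


def test_shrinkage_limit_predictions_vanish():
    rng = np.random.default_rng(7)
    X = pd.DataFrame({"a": rng.standard_normal(100)})
    t, d = _weibull_outcomes(rng, X["a"].to_numpy())
    ens = fit_gbm(X, t, d, nu=1e-9, n_max=10, inner_folds=0, seed=0)
    assert np.abs(ens.predict(X)).max() < 1e-6


def test_empty_ensemble_predicts_zero():
    X = pd.DataFrame({"a": [1.0, 2.0]})
    ens = BoostedCoxEnsemble(binner=Binner().fit(X))
    np.testing.assert_array_equal(predict_risk(ens, X), [0.0, 0.0])


def test_single_depth_zero_tree_scales_by_nu():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    tree = RegressionTree(nodes=[Node(value=4.0)])
    ens = BoostedCoxEnsemble(binner=Binner().fit(X), trees=[tree], nu=0.05, n_trees=1)
    np.testing.assert_allclose(ens.predict(X), 0.05 * 4.0)


def test_prediction_is_sum_over_trees():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.standard_normal((120, 5)), columns=list("abcde"))
    t, d = _weibull_outcomes(rng, X["a"].to_numpy())
    ens = fit_gbm(X, t, d, nu=0.1, n_max=20, inner_folds=0, seed=3)
    rows = X.iloc[:10]
    C = ens.binner.transform(rows)
    brute = sum(ens.nu * tr.predict_codes(C) for tr in ens.trees[: ens.n_trees])
    np.testing.assert_allclose(ens.predict(rows), brute, atol=1e-12)


def test_unknown_feature_column_rejected():
    rng = np.random.default_rng(9)
    X = pd.DataFrame({"a": rng.standard_normal(80), "b": rng.standard_normal(80)})
    t, d = _weibull_outcomes(rng, X["a"].to_numpy())
    ens = fit_gbm(X, t, d, n_max=5, inner_folds=0, seed=0)
    with pytest.raises(KeyError, match="schema"):
        ens.predict(X[["a"]])


def test_importance_normalization_and_single_feature():
    rng = np.random.default_rng(10)
    X = pd.DataFrame({"a": rng.standard_normal(150)})
    t, d = _weibull_outcomes(rng, 1.5 * X["a"].to_numpy())
    ens = fit_gbm(X, t, d, n_max=20, inner_folds=0, seed=1)
    imp = variable_importance(ens)
    assert imp["a"] == pytest.approx(100.0)
    assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)


def test_duplicated_planted_features_share_influence():
    rng = np.random.default_rng(11)
    n = 400
    a = rng.standard_normal(n)
    t, d = _weibull_outcomes(rng, 1.5 * a)
    noise = rng.standard_normal(n)
    X_two = pd.DataFrame({"a1": a, "a2": a.copy(), "n1": noise})
    ens = fit_gbm(X_two, t, d, nu=0.1, n_max=40, inner_folds=0, seed=2)
    imp = variable_importance(ens)
    assert imp["a1"] > 0 and imp["a2"] > 0
    X_one = pd.DataFrame({"a1": a, "n1": noise})
    single = variable_importance(fit_gbm(X_one, t, d, nu=0.1, n_max=40,
                                         inner_folds=0, seed=2))
    assert imp["a1"] + imp["a2"] == pytest.approx(single["a1"], abs=10.0)


def test_training_loss_monotone_without_bagging():
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
    t, d = _weibull_outcomes(rng, X["a"].to_numpy())
    ens = fit_gbm(X, t, d, nu=0.1, n_max=40, inner_folds=0, bag_fraction=1.0, seed=0)
    loss = ens.training_log["train_loss"].to_numpy()
    assert (np.diff(loss) <= 1e-9).all()


def test_patient_order_permutation_invariance():
    rng = np.random.default_rng(13)
    X = pd.DataFrame(rng.standard_normal((150, 6)), columns=list("abcdef"))
    t, d = _weibull_outcomes(rng, X["a"].to_numpy() - X["b"].to_numpy())
    ens1 = fit_gbm(X, t, d, nu=0.1, n_max=25, inner_folds=0, bag_fraction=1.0, seed=5)
    perm = rng.permutation(150)
    ens2 = fit_gbm(X.iloc[perm].reset_index(drop=True), t[perm], d[perm],
                   nu=0.1, n_max=25, inner_folds=0, bag_fraction=1.0, seed=5)
    np.testing.assert_allclose(ens1.predict(X), ens2.predict(X), atol=1e-10)


def test_planted_features_rank_top_among_many():
    # 5 informative of 200 features at n=600 recovered in the influence top 10
    hits = 0
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        n, p = 600, 200
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
        lp = (0.6 * X["x0"] - 0.6 * X["x1"] + 0.6 * X["x2"]
              - 0.5 * X["x3"] + 0.5 * X["x4"]).to_numpy()
        t, d = _weibull_outcomes(rng, lp)
        ens = fit_gbm(X, t, d, nu=0.1, n_max=100, inner_folds=0, seed=seed)
        imp = variable_importance(ens)
        top10 = sorted(imp, key=imp.get, reverse=True)[:10]
        if all(f"x{i}" in top10 for i in range(5)):
            hits += 1
    assert hits >= 2


def test_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(14)
    X = pd.DataFrame({
        "num": rng.standard_normal(120),
        "cat": pd.Categorical(rng.choice(list("uvw"), 120)),
    })
    t, d = _weibull_outcomes(rng, np.where(X["cat"] == "u", 1.0, -0.5))
    ens = fit_gbm(X, t, d, n_max=15, inner_folds=0, seed=4)
    path = tmp_path / "model.json"
    ens.to_json(path)
    loaded = BoostedCoxEnsemble.from_json(path)
    np.testing.assert_allclose(ens.predict(X), loaded.predict(X), atol=1e-12)


# ---------------------------------------------------------------- fusion
def test_single_modality_fusion_equals_plain_fit():
    rng = np.random.default_rng(15)
    X = pd.DataFrame(rng.standard_normal((200, 10)), columns=[f"x{i}" for i in range(10)])
    t, d = _weibull_outcomes(rng, 1.5 * X["x0"].to_numpy())
    params = dict(nu=0.1, n_max=30, inner_folds=3)
    plain = fit_gbm(X, t, d, seed=9, **params)
    fused = two_step_fusion({"only": X}, t, d, seed=9, **params)
    np.testing.assert_allclose(plain.predict(X), fused.predict(X), atol=1e-12)


def test_fusion_final_features_subset_of_step_one_union():
    rng = np.random.default_rng(16)
    n = 250
    clin = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"c{i}" for i in range(5)])
    snps = pd.DataFrame(rng.integers(0, 3, (n, 8)).astype(float),
                        columns=[f"s{i}" for i in range(8)])
    t, d = _weibull_outcomes(rng, 1.5 * clin["c0"].to_numpy())
    res = two_step_fusion({"clinical": clin, "snps": snps}, t, d, seed=1,
                          nu=0.1, n_max=25, inner_folds=3)
    union = set(res.selected["clinical"]) | set(res.selected["snps"])
    used = {f for f, v in res.importance().items() if v > 0}
    assert used <= union
    assert set(res.model.feature_names) <= union


def test_fusion_signal_only_in_clinical_block():
    rng = np.random.default_rng(17)
    n = 300
    clin = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"c{i}" for i in range(5)])
    noise = pd.DataFrame(rng.standard_normal((n, 30)), columns=[f"z{i}" for i in range(30)])
    lp = 1.5 * clin["c0"].to_numpy() - 1.0 * clin["c1"].to_numpy()
    t, d = _weibull_outcomes(rng, lp)
    tr = np.arange(200)
    te = np.arange(200, 300)
    params = dict(nu=0.1, n_max=40, inner_folds=3)
    fused = two_step_fusion(
        {"clinical": clin.iloc[tr], "noise": noise.iloc[tr]}, t[tr], d[tr], seed=2, **params
    )
    clin_only = two_step_fusion({"clinical": clin.iloc[tr]}, t[tr], d[tr], seed=2, **params)
    joined_te = pd.concat([clin.iloc[te], noise.iloc[te]], axis=1)
    c_fused = harrell_c(fused.predict(joined_te), t[te], d[te])
    c_clin = harrell_c(clin_only.predict(clin.iloc[te]), t[te], d[te])
    assert abs(c_fused - c_clin) <= 0.03


def test_fusion_rejects_overlapping_columns():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="duplicate"):
        two_step_fusion({"m1": X, "m2": X}, np.ones(3), np.ones(3, dtype=int))
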
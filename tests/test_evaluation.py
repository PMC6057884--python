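"""Concordance, survival curves, IPCW Brier, CV, stratification and FDR tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adprog.evaluation import (
    by_fdr,
    brier_ipcw,
    group_feature_tests,
    harrell_c,
    km_survival,
    log_rank_test,
    nelson_aalen,
    prediction_error_curve,
    repeated_cv,
    stratify_extremes,
)
from adprog.evaluation.curves import breslow_baseline, censoring_km

from conftest import random_censored


# ---------------------------------------------------------------- concordance
def brute_force_c(risks, times, events):
    """Literal pair-enumeration oracle for Harrell's C."""
    conc = comp = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            comp += 1
            if risks[i] > risks[j]:
                conc += 1
            elif risks[i] == risks[j]:
                conc += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp


def test_harrell_c_hand_example():
    assert harrell_c([4, 3, 1, 2], [1, 2, 3, 4], [1, 1, 1, 1]) == pytest.approx(5 / 6)


def test_harrell_c_perfect_and_reversed_order():
    t = np.array([4.0, 3.0, 2.0, 1.0])
    r = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.ones(4, dtype=int)
    assert harrell_c(r, t, d) == 1.0
    assert harrell_c(-r, t, d) == 0.0


def test_harrell_c_all_ties_is_half():
    assert harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5


def test_harrell_c_no_comparable_pairs_raises():
    with pytest.raises(ValueError, match="comparable"):
        harrell_c([1, 2], [1, 2], [0, 0])


def test_harrell_c_matches_brute_force_oracle(rng):
    for _ in range(50):
        r, t, d = random_censored(rng)
        assert harrell_c(r, t, d) == pytest.approx(brute_force_c(r, t, d), abs=1e-12)


def test_harrell_c_agrees_with_reference_implementation(rng):
    from sksurv.metrics import concordance_index_censored
    for _ in range(10):
        r, t, d = random_censored(rng)
        t = t + rng.random(len(t)) * 0.01  # break time ties: conventions differ there
        ours = harrell_c(r, t, d)
        ref = concordance_index_censored(d.astype(bool), t, r)[0]
        assert ours == pytest.approx(ref, abs=1e-10)


# ---------------------------------------------------------------- KM / NA
def test_km_product_limit_by_hand():
    S = km_survival([1, 2], [1, 1])
    assert S(0.5) == 1.0
    assert S(1) == pytest.approx(0.5)
    assert S(2) == pytest.approx(0.0)


def test_km_all_censored_stays_at_one():
    S = km_survival([3, 5, 7], [0, 0, 0])
    assert S(10) == 1.0


def test_km_late_censoring_does_not_change_event_steps():
    S1 = km_survival([1, 2], [1, 1])
    S2 = km_survival([1, 2, 9], [1, 1, 0])
    # with 3 at risk: S(1)=2/3, S(2)=1/3; late censoring leaves steps at events
    assert S2(1) == pytest.approx(2 / 3)
    assert S2(5) == S2(2)


def test_nelson_aalen_hand_example():
    H = nelson_aalen([1, 2], [1, 1])
    assert H(0.5) == 0.0
    assert H(1) == pytest.approx(0.5)
    assert H(2) == pytest.approx(1.5)


def test_nelson_aalen_all_censored_is_zero():
    H = nelson_aalen([1, 2, 3], [0, 0, 0])
    assert H(5) == 0.0


def test_nelson_aalen_single_event_jump():
    H = nelson_aalen([1.0] * 10, [1] + [0] * 9)
    assert H(1) == pytest.approx(1 / 10)


# ---------------------------------------------------------------- Brier
def test_brier_hand_example_no_censoring():
    assert brier_ipcw([0.8, 0.2], [3, 10], [1, 0], t=5) == pytest.approx(0.64)


def test_brier_perfect_oracle_is_zero():
    S = np.array([0.0, 1.0, 0.0, 1.0])
    t = np.array([1.0, 9.0, 2.0, 8.0])
    d = np.array([1, 1, 1, 1])
    assert brier_ipcw(S, t, d, t=5) == 0.0


def test_brier_constant_half_is_quarter():
    t = np.array([1.0, 9.0, 2.0, 8.0])
    assert brier_ipcw([0.5] * 4, t, np.ones(4, int), t=5) == pytest.approx(0.25)


def test_brier_without_censoring_equals_mse(rng):
    n = 60
    t = rng.exponential(10, n)
    d = np.ones(n, dtype=int)
    S = rng.random(n)
    for horizon in (2.0, 5.0, 9.0):
        alive = (t > horizon).astype(float)
        assert brier_ipcw(S, t, d, horizon) == pytest.approx(
            np.mean((alive - S) ** 2), abs=1e-12
        )


def test_brier_zero_censoring_survival_rejected():
    # everyone censored by t=2 -> G(3) = 0
    with pytest.raises(ValueError, match="G"):
        brier_ipcw([0.5, 0.5], [1.0, 2.0], [0, 0], t=3.0)


def test_brier_agrees_with_reference_implementation(rng):
    from sksurv.metrics import brier_score as sk_brier
    n = 100
    t = rng.exponential(10, n) + 0.1
    d = rng.integers(0, 2, n)
    d[np.argmax(t)] = 1
    S = rng.random(n)
    y = np.array([(bool(e), tt) for e, tt in zip(d, t)],
                 dtype=[("event", bool), ("time", float)])
    horizon = np.quantile(t, 0.4)
    _, ref = sk_brier(y, y, S[:, None], [horizon])
    ours = brier_ipcw(S, t, d, horizon)
    assert ours == pytest.approx(ref[0], rel=1e-6)


# ---------------------------------------------------------------- curves
def test_curve_model_equal_to_km_reference(rng):
    n = 80
    t = rng.exponential(10, n)
    d = rng.integers(0, 2, n)
    d[np.argmax(t)] = 1
    S = km_survival(t, d)
    curve = prediction_error_curve(
        lambda idx, h: np.full(len(idx), S(h)), t, d, grid=[2, 5, 8]
    )
    np.testing.assert_allclose(curve.model, curve.reference, atol=1e-12)


def test_curve_empty_grid():
    curve = prediction_error_curve(lambda idx, h: np.ones(len(idx)),
                                   [1, 2, 3], [1, 1, 0], grid=[])
    assert curve.grid.size == 0 and curve.model.size == 0


def test_breslow_baseline_no_covariates_matches_nelson_aalen(rng):
    n = 50
    t = rng.exponential(10, n)
    d = rng.integers(0, 2, n)
    d[0] = 1
    H_breslow = breslow_baseline(np.zeros(n), t, d)
    H_na = nelson_aalen(t, d)
    for h in np.quantile(t, [0.2, 0.5, 0.8]):
        assert H_breslow(h) == pytest.approx(H_na(h), rel=1e-9)


# ---------------------------------------------------------------- repeated CV
class _ConstantLearner:
    def fit(self, X, times, events, seed):
        return self

    def predict(self, X):
        # tiny deterministic jitter: constant risks have no comparable ordering
        return np.arange(len(X)) * 1e-12

    def importance(self):
        return {}


class _OracleLearner:
    """Predicts the first feature directly (used to exercise the CV plumbing)."""

    def fit(self, X, times, events, seed):
        return self

    def predict(self, X):
        return X.iloc[:, 0].to_numpy()

    def importance(self):
        return {"x0": 100.0}


def _cv_data(rng, n=120):
    X = pd.DataFrame({"x0": rng.standard_normal(n), "x1": rng.standard_normal(n)})
    t = np.exp(-X["x0"].to_numpy()) * rng.exponential(10, n)
    d = rng.integers(0, 2, n)
    if d.sum() < 10:
        d[:10] = 1
    return X, t, d


def test_cv_constant_predictor_is_chance(rng):
    X, t, d = _cv_data(rng)
    res = repeated_cv(X, t, d, _ConstantLearner, k=4, repeats=2, seed=1)
    assert res.mean_c() == pytest.approx(0.5, abs=0.06)


def test_cv_selection_counts_bounded_and_reproducible(rng):
    X, t, d = _cv_data(rng)
    res1 = repeated_cv(X, t, d, _OracleLearner, k=5, repeats=2, seed=3)
    res2 = repeated_cv(X, t, d, _OracleLearner, k=5, repeats=2, seed=3)
    assert res1.n_models == 10
    assert res1.selection_counts["x0"] == 10 and res1.selection_counts["x1"] == 0
    pd.testing.assert_frame_equal(res1.c_index, res2.c_index)


# ---------------------------------------------------------------- stratify
def test_stratify_group_sizes():
    rng = np.random.default_rng(0)
    hi, lo = stratify_extremes(rng.standard_normal(930), q=0.1)
    assert len(hi) == len(lo) == 93
    hi2, lo2 = stratify_extremes(rng.standard_normal(20), q=0.1)
    assert len(hi2) == len(lo2) == 2


def test_stratify_order_statistics():
    hi, lo = stratify_extremes(np.arange(1, 101, dtype=float), q=0.1)
    np.testing.assert_array_equal(hi, np.arange(90, 100))
    np.testing.assert_array_equal(lo, np.arange(0, 10))


def test_stratify_constant_risks_rejected():
    with pytest.raises(ValueError, match="constant"):
        stratify_extremes(np.ones(100), q=0.1)


def test_logrank_identical_groups():
    t = np.array([1.0, 2, 3, 4, 5, 6])
    d = np.array([1, 0, 1, 1, 0, 1])
    stat, p = log_rank_test((t, d), (t.copy(), d.copy()))
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_logrank_separated_hazards(rng):
    hits = 0
    for _ in range(10):
        tA = rng.exponential(1.0, 100)
        tB = rng.exponential(5.0, 100)
        _, p = log_rank_test((tA, np.ones(100, int)), (tB, np.ones(100, int)))
        hits += p < 0.001
    assert hits >= 9


def test_logrank_matches_hand_computation():
    # 6 patients, all events: O-E and hypergeometric variance summed by hand
    tA = np.array([1.0, 3.0, 5.0])
    tB = np.array([2.0, 4.0, 6.0])
    dA = dB = np.ones(3, dtype=int)
    # at t=1: nA=3,nB=3, E=.5, V=.25 | t=2: 2,3 E=.4 V=.24 | t=3: 2,2 E=.5 V=.25
    # t=4: 1,2 E=1/3 V=2/9 | t=5: 1,1 E=.5 V=.25 | t=6: 0,1 E=0 V=0
    O_A = 3.0
    E_A = 0.5 + 0.4 + 0.5 + 1 / 3 + 0.5 + 0.0
    V = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.25 + 0.0
    expected = (O_A - E_A) ** 2 / V
    stat, _ = log_rank_test((tA, dA), (tB, dB))
    assert stat == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------- group tests
def test_group_tests_identical_groups_not_significant(rng):
    df = pd.DataFrame({"a": rng.standard_normal(60),
                       "b": pd.Categorical(rng.choice(["x", "y"], 60))})
    res = group_feature_tests(df, df.copy())
    assert (res["q"] > 0.5).all()


def test_group_tests_large_shift_detected(rng):
    n = 93
    high = pd.DataFrame({"a": rng.standard_normal(n) + 3.0,
                         "noise": rng.standard_normal(n)})
    low = pd.DataFrame({"a": rng.standard_normal(n),
                        "noise": rng.standard_normal(n)})
    res = group_feature_tests(high, low).set_index("feature")
    assert res.loc["a", "q"] < 1e-9
    assert res.loc["noise", "q"] > 0.05


def test_group_tests_constant_feature_skipped(rng):
    high = pd.DataFrame({"c": np.ones(20), "a": rng.standard_normal(20)})
    low = pd.DataFrame({"c": np.ones(20), "a": rng.standard_normal(20)})
    res = group_feature_tests(high, low).set_index("feature")
    assert res.loc["c", "test"] == "skipped"
    assert res.loc["c", "q"] == 1.0


def test_group_tests_discrete_uses_chi2(rng):
    n = 80
    high = pd.DataFrame({"g": pd.Categorical(["x"] * 70 + ["y"] * 10)})
    low = pd.DataFrame({"g": pd.Categorical(["x"] * 10 + ["y"] * 70)})
    res = group_feature_tests(high, low)
    assert res.iloc[0]["test"] == "chi2"
    assert res.iloc[0]["q"] < 1e-9


# ---------------------------------------------------------------- BY FDR
def test_by_adjustment_hand_examples():
    np.testing.assert_allclose(by_fdr([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055])
    np.testing.assert_allclose(by_fdr([0.001, 0.5]), [0.003, 0.75])
    assert by_fdr([0.2]) == pytest.approx([0.2])


def test_by_equal_pvalues_equal_adjustments():
    out = by_fdr([0.04, 0.04, 0.04, 0.04])
    assert np.all(out == out[0])


def test_by_dominates_bh_and_is_monotone(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(20):
        p = rng.random(rng.integers(2, 40))
        ours = by_fdr(p)
        bh = multipletests(p, method="fdr_bh")[1]
        sm_by = multipletests(p, method="fdr_by")[1]
        assert (ours >= bh - 1e-12).all()
        np.testing.assert_allclose(ours, sm_by, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(ours[order]) >= -1e-12).all()


def test_by_rejects_out_of_range():
    with pytest.raises(ValueError):
        by_fdr([0.5, 1.5])
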
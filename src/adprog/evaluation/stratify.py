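"""Extreme-quantile risk stratification and group difference testing."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


def stratify_extremes(risks, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the upper-q and lower-q risk groups (each of size ceil(q n)).

    Ties are broken by original order (stable sort) so the groups are always
    disjoint and exactly ceil(q n) large. Constant risks are rejected: no
    meaningful extremes exist.
    """
    r = np.asarray(risks, dtype=float)
    n = len(r)
    if n < 2.0 / q:
        raise ValueError("too few patients for the requested quantile")
    if np.all(r == r[0]):
        raise ValueError("risk scores are constant; stratification undefined")
    m = math.ceil(q * n)
    order = np.argsort(r, kind="stable")
    low = order[:m]
    high = order[-m:]
    return np.sort(high), np.sort(low)


def log_rank_test(
    groupA: tuple[np.ndarray, np.ndarray], groupB: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Two-sample log-rank test; each group is (times, events). Returns (chi2, p)."""
    tA, dA = (np.asarray(x) for x in groupA)
    tB, dB = (np.asarray(x) for x in groupB)
    if len(tA) == 0 or len(tB) == 0:
        raise ValueError("both groups must be nonempty")
    if dA.sum() + dB.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(tA, tB, event_observed_A=dA, event_observed_B=dB)
    return float(res.test_statistic), float(res.p_value)


def by_fdr(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values (valid under arbitrary dependence).

    Step-up adjustment q_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j) with the
    harmonic-sum inflation c(m) = sum_{i=1..m} 1/i; elementwise >= the
    Benjamini-Hochberg adjustment and monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def group_feature_tests(
    high: pd.DataFrame,
    low: pd.DataFrame,
    roles: dict[str, str] | None = None,
    continuous_roles: tuple[str, ...] = ("neuropsych", "imaging", "age", "pathway", "component", "genomic"),
) -> pd.DataFrame:
    """Per-feature two-group tests with BY-adjusted q-values.

    Continuous features use the Wilcoxon rank-sum (Mann-Whitney) test,
    discrete/categorical ones a contingency chi-square. The choice follows the
    column dtype unless ``roles`` tags it explicitly. Constant features are
    skipped with q = 1 recorded. Returns a DataFrame (feature, test, p, q).
    """
    rows = []
    for col in high.columns:
        a, b = high[col], low[col]
        if isinstance(a.dtype, pd.CategoricalDtype) or a.dtype == object or (
            roles is not None and roles.get(col) not in continuous_roles and roles.get(col) is not None
        ):
            tab = pd.crosstab(
                pd.concat([a, b]).reset_index(drop=True),
                np.repeat(["high", "low"], [len(a), len(b)]),
            )
            if tab.shape[0] < 2 or (tab.sum(axis=1) == 0).any():
                rows.append((col, "skipped", np.nan, None))
                continue
            stat, p, _, _ = stats.chi2_contingency(tab.to_numpy())
            rows.append((col, "chi2", p, None))
        else:
            av = a.to_numpy(dtype=float)
            bv = b.to_numpy(dtype=float)
            av, bv = av[~np.isnan(av)], bv[~np.isnan(bv)]
            pooled = np.concatenate([av, bv])
            if len(av) == 0 or len(bv) == 0 or np.all(pooled == pooled[0]):
                rows.append((col, "skipped", np.nan, None))
                continue
            _, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
            rows.append((col, "wilcoxon", p, None))
    df = pd.DataFrame(rows, columns=["feature", "test", "p", "q"])
    tested = df["test"] != "skipped"
    q = np.ones(len(df))
    if tested.any():
        q[tested.to_numpy()] = by_fdr(df.loc[tested, "p"].to_numpy())
    df["q"] = q
    return df
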
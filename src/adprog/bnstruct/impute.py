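"""Iterative random-forest imputation for mixed continuous/categorical tables.

missForest-style loop: initialize missing cells by column mean (continuous)
or mode (categorical); then, cycling over variables in order of increasing
missingness, fit a random forest of that variable on all others and replace
its missing cells by predictions. Iterate until the normalized change between
successive imputations increases (or ``max_iter`` is reached) and return the
previous (best) imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor


def _is_categorical(s: pd.Series) -> bool:
    return isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object


def iterative_rf_impute(
    table: pd.DataFrame,
    max_iter: int = 10,
    seed: int = 0,
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Impute missing values in place of NaN / missing categories.

    Every column must have at least one observed value. A table with no
    missing cells is returned unchanged (a copy).
    """
    miss = pd.DataFrame(
        {c: table[c].isna() for c in table.columns}, index=table.index
    )
    all_missing = [c for c in table.columns if miss[c].all()]
    if all_missing:
        raise ValueError(f"columns entirely missing: {all_missing}")
    if not miss.to_numpy().any():
        return table.copy()

    cat_cols = [c for c in table.columns if _is_categorical(table[c])]
    cats = {c: table[c].astype("category").cat.categories for c in cat_cols}

    # numeric working matrix; categoricals as codes
    work = pd.DataFrame(index=table.index)
    for c in table.columns:
        if c in cat_cols:
            work[c] = table[c].astype(pd.CategoricalDtype(cats[c])).cat.codes.astype(float)
            work.loc[miss[c], c] = np.nan
        else:
            work[c] = table[c].astype(float)

    # initialization: mean / mode
    for c in table.columns:
        if c in cat_cols:
            fill = work[c].mode(dropna=True).iloc[0]
        else:
            fill = work[c].mean(skipna=True)
        work.loc[miss[c], c] = fill

    order = sorted(table.columns, key=lambda c: miss[c].sum())
    targets = [c for c in order if miss[c].any()]
    rng = np.random.default_rng(seed)

    def norm_change(curr: pd.DataFrame, prev: pd.DataFrame) -> float:
        num = den = 0.0
        for c in targets:
            a = curr[c].to_numpy()
            b = prev[c].to_numpy()
            if c in cat_cols:
                num += (a != b).sum()
                den += miss[c].sum()
            else:
                num += ((a - b) ** 2).sum()
                den += (a**2).sum()
        return num / max(den, 1e-300)

    best = work.copy()
    prev_delta = np.inf
    for _ in range(max_iter):
        previous = work.copy()
        for c in targets:
            others = [x for x in table.columns if x != c]
            X_obs = work.loc[~miss[c], others]
            X_mis = work.loc[miss[c], others]
            y_obs = work.loc[~miss[c], c]
            rs = int(rng.integers(2**31))
            if c in cat_cols:
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rs, n_jobs=1
                )
            else:
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rs, n_jobs=1
                )
            model.fit(X_obs, y_obs)
            work.loc[miss[c], c] = model.predict(X_mis)
        delta = norm_change(work, previous)
        if delta >= prev_delta:
            work = previous  # last iteration made things worse; keep the better one
            break
        best = work.copy()
        prev_delta = delta

    out = pd.DataFrame(index=table.index)
    for c in table.columns:
        if c in cat_cols:
            codes = np.clip(np.round(best[c].to_numpy()), 0, len(cats[c]) - 1).astype(int)
            out[c] = pd.Categorical.from_codes(codes, categories=cats[c])
        else:
            out[c] = best[c]
    return out
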
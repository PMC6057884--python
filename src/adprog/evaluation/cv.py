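"""Repeated, event-stratified cross-validation with feature-selection counts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .concordance import harrell_c

log = logging.getLogger(__name__)


class SurvivalLearner(Protocol):
    """fit(X, times, events, seed) -> fitted object with predict(X) and
    importance() -> dict[str, float]."""

    def fit(self, X: pd.DataFrame, times: np.ndarray, events: np.ndarray, seed: int): ...


@dataclass
class CVResult:
    c_index: pd.DataFrame                 # columns: repeat, fold, c
    selection_counts: dict[str, int]      # feature -> #models with importance > 0
    n_models: int
    held_out_risk: pd.DataFrame           # patient_id, repeat, risk
    fold_models: list = field(default_factory=list, repr=False)

    def mean_c(self) -> float:
        return float(self.c_index["c"].mean())

    def selection_frequency(self) -> pd.Series:
        s = pd.Series(self.selection_counts, dtype=float) / self.n_models
        return s.sort_values(ascending=False)


def stratified_folds(
    events: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels 0..k-1, stratified by event status; refolds (with warning)
    if some fold ends up without any event."""
    d = np.asarray(events, dtype=int)
    n = len(d)
    for attempt in range(20):
        folds = np.empty(n, dtype=int)
        for val in (0, 1):
            idx = np.where(d == val)[0]
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % k
        ok = all((d[folds == f] == 1).any() for f in range(k))
        if ok:
            return folds
        log.warning("fold without events on attempt %d; refolding", attempt)
    raise ValueError("could not build event-containing folds (too few events?)")


def repeated_cv(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    learner_factory: Callable[[], SurvivalLearner],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """k-fold cross-validation repeated ``repeats`` times.

    Per held-out fold: Harrell's C of the learner's risk predictions, and the
    set of features carrying nonzero importance. Selection counts accumulate
    over all repeats x folds models. Reproducible under ``seed``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ss = np.random.SeedSequence([int(seed), 917])
    rows = []
    risk_rows = []
    counts: dict[str, int] = {c: 0 for c in X.columns}
    models = []
    n_models = 0
    for rep, child in enumerate(ss.spawn(repeats)):
        rng = np.random.default_rng(child)
        folds = stratified_folds(events, k, rng)
        fit_seed_base = int(rng.integers(2**31))
        for f in range(k):
            test = folds == f
            train = ~test
            model = learner_factory().fit(
                X.iloc[train], times[train], events[train],
                seed=(fit_seed_base + f) % (2**31),
            )
            risk = np.asarray(model.predict(X.iloc[test]), dtype=float)
            try:
                c = harrell_c(risk, times[test], events[test])
            except ValueError:
                c = np.nan
            rows.append((rep, f, c))
            for feat, imp in model.importance().items():
                if imp > 0:
                    counts[feat] = counts.get(feat, 0) + 1
            for pid, rk in zip(X.index[test], risk):
                risk_rows.append((pid, rep, rk))
            if keep_models:
                models.append(model)
            n_models += 1
    return CVResult(
        c_index=pd.DataFrame(rows, columns=["repeat", "fold", "c"]),
        selection_counts=counts,
        n_models=n_models,
        held_out_risk=pd.DataFrame(risk_rows, columns=["patient_id", "repeat", "risk"]),
        fold_models=models,
    )
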
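"""Survival / hazard step functions and IPCW Brier prediction-error curves.

Kaplan-Meier and Nelson-Aalen estimation delegate to lifelines; the inverse
probability-of-censoring-weighted Brier score and the Breslow baseline-hazard
conversion from boosted log-hazard scores to survival curves are implemented
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from lifelines import KaplanMeierFitter, NelsonAalenFitter

log = logging.getLogger(__name__)


class StepFunction:
    """Right-continuous step function defined by jump times and values."""

    def __init__(self, x: np.ndarray, y: np.ndarray, init: float):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.init = init

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.maximum(idx, 0)], self.init)
        return float(out) if out.ndim == 0 else out


def km_survival(times, events) -> StepFunction:
    """Kaplan-Meier product-limit estimate S(t) as a right-continuous step function."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy(), init=1.0)


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard (d/n increments), nondecreasing with H(0)=0."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(t, event_observed=d)
    ch = naf.cumulative_hazard_
    return StepFunction(ch.index.to_numpy(), ch.iloc[:, 0].to_numpy(), init=0.0)


def censoring_km(times, events) -> StepFunction:
    """Kaplan-Meier of the censoring distribution G(t) (event roles flipped)."""
    return km_survival(times, 1 - np.asarray(events, dtype=int))


def brier_ipcw(
    predicted_survival_at_t: np.ndarray,
    times,
    events,
    t: float,
    G: StepFunction | None = None,
) -> float:
    """IPCW Brier score at horizon ``t``.

    BS(t) = mean over patients of
        S_hat(t|i)^2 / G(T_i-)      if T_i <= t and event
        (1 - S_hat(t|i))^2 / G(t)   if T_i > t
    with G the censoring-distribution Kaplan-Meier. Patients censored before
    ``t`` contribute 0 (their weight is carried by the IPCW reweighting).
    Reduces to the plain mean squared error of the survival indicator when no
    censoring is present. Raises when G(t) = 0.
    """
    S = np.asarray(predicted_survival_at_t, dtype=float)
    T = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if G is None:
        G = censoring_km(T, d)
    Gt = G(t)
    if Gt <= 0:
        raise ValueError(f"censoring survival G({t}) = 0; drop this time point")
    before = (T <= t) & (d == 1)
    after = T > t
    # G evaluated just before the event time
    G_Ti = np.maximum(G(np.maximum(T - 1e-12, 0.0)), 1e-12)
    contrib = np.zeros(len(T))
    contrib[before] = (S[before] ** 2) / G_Ti[before]
    contrib[after] = ((1.0 - S[after]) ** 2) / Gt
    return float(contrib.mean())


def breslow_baseline(scores, times, events) -> StepFunction:
    """Breslow estimate of the baseline cumulative hazard H0(t).

    H0(t) = sum over event times t_j <= t of d_j / sum_{k in risk set} exp(f_k),
    so S(t | x) = exp(-H0(t) exp(f(x))).
    """
    f = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t_s, d_s, f_s = t[order], d[order], f[order]
    exp_f = np.exp(f_s - f_s.max())
    # risk-set sums via suffix cumulation
    suffix = np.cumsum(exp_f[::-1])[::-1]
    uniq, first = np.unique(t_s, return_index=True)
    jumps = []
    H = 0.0
    vals = []
    for u, i0 in zip(uniq, first):
        at = t_s == u
        dj = d_s[at].sum()
        if dj > 0:
            H += dj / suffix[i0] * np.exp(-f_s.max())  # undo stabilization
            jumps.append(u)
            vals.append(H)
    if not jumps:
        return StepFunction(np.array([0.0]), np.array([0.0]), init=0.0)
    return StepFunction(np.array(jumps), np.array(vals), init=0.0)


@dataclass
class PredictionErrorCurve:
    grid: np.ndarray
    model: np.ndarray        # mean across folds
    reference: np.ndarray    # Kaplan-Meier reference
    model_sd: np.ndarray | None = None
    reference_sd: np.ndarray | None = None


def prediction_error_curve(
    survival_fn: Callable[[np.ndarray, float], np.ndarray],
    times,
    events,
    grid,
    reference: StepFunction | None = None,
) -> PredictionErrorCurve:
    """Brier-score curve of a model against the Kaplan-Meier reference.

    ``survival_fn(patients_index_array, t)`` returns per-patient predicted
    survival probabilities at horizon ``t`` (the index array selects which
    patients; pass-through implementations may ignore it). ``reference``
    defaults to the KM estimate on the same data. Grid points where the
    censoring distribution hits zero are dropped with a warning.
    """
    T = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if reference is None:
        reference = km_survival(T, d)
    G = censoring_km(T, d)
    idx = np.arange(len(T))
    mod, ref, kept = [], [], []
    for t in grid:
        if G(t) <= 0:
            log.warning("dropping t=%g: censoring KM reaches 0", t)
            continue
        S_mod = np.asarray(survival_fn(idx, t), dtype=float)
        S_ref = np.full(len(T), reference(t))
        mod.append(brier_ipcw(S_mod, T, d, t, G=G))
        ref.append(brier_ipcw(S_ref, T, d, t, G=G))
        kept.append(t)
    return PredictionErrorCurve(np.array(kept), np.array(mod), np.array(ref))
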
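"""Cox partial-likelihood loss, working residuals and curvature.

Breslow handling of tied event times throughout: the partial log-likelihood is

    l(f) = sum_{i: d_i = 1} [ f_i - log sum_{k: t_k >= t_i} exp(f_k) ],

its gradient with respect to f_i (the "working residual" boosted against) is

    r_i = d_i - exp(f_i) * sum_{j: t_j <= t_i, d_j = 1} d_j / S_j,
    S_j = sum_{k: t_k >= t_j} exp(f_k),

and the diagonal of the Hessian of -l is

    h_i = exp(f_i) * sum_j d_j / S_j  -  exp(2 f_i) * sum_j d_j / S_j^2,

both sums over distinct event times at or before t_i. All three are computed
in O(n log n) via a single sort and suffix/prefix cumulations.
"""

from __future__ import annotations

import numpy as np


def _prepare(scores, times, events):
    f = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if not (len(f) == len(t) == len(d)):
        raise ValueError("scores, times and events must share one length")
    if d.sum() == 0:
        raise ValueError("at least one event is required")
    return f, t, d


def cox_partial_loglik(scores, times, events) -> float:
    """Breslow-form Cox partial log-likelihood (higher is better).

    Invariant to adding a constant to all scores. n = 1 with an event gives 0.
    """
    f, t, d = _prepare(scores, times, events)
    shift = f.max()
    order = np.argsort(t, kind="stable")
    f_s, t_s, d_s = f[order] - shift, t[order], d[order]
    exp_f = np.exp(f_s)
    suffix = np.cumsum(exp_f[::-1])[::-1]  # suffix[i] = sum_{k >= i} exp(f_k)
    ll = 0.0
    i = 0
    n = len(f_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        dj = d_s[i:j].sum()
        if dj > 0:
            ll += f_s[i:j][d_s[i:j] == 1].sum() - dj * np.log(suffix[i])
        i = j
    return float(ll)


def _risk_sums(f_s, t_s, d_s):
    """Per-sample cumulative sums A_i = sum_{events <= t_i} d_j/S_j and
    B_i = sum d_j/S_j^2, on time-sorted arrays."""
    exp_f = np.exp(f_s)
    suffix = np.cumsum(exp_f[::-1])[::-1]
    n = len(f_s)
    A = np.zeros(n)
    B = np.zeros(n)
    accA = accB = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        dj = d_s[i:j].sum()
        if dj > 0:
            accA += dj / suffix[i]
            accB += dj / suffix[i] ** 2
        A[i:j] = accA
        B[i:j] = accB
        i = j
    return A, B, exp_f


def cox_negative_gradient(scores, times, events) -> np.ndarray:
    """Working residuals r_i = d_i - exp(f_i) A_i; they sum to zero exactly."""
    f, t, d = _prepare(scores, times, events)
    shift = f.max()
    order = np.argsort(t, kind="stable")
    f_s, t_s, d_s = f[order] - shift, t[order], d[order]
    A, _, exp_f = _risk_sums(f_s, t_s, d_s)
    r_s = d_s - exp_f * A
    r = np.empty_like(r_s)
    r[order] = r_s
    return r


def cox_hessian_diag(scores, times, events) -> np.ndarray:
    """Diagonal curvature h_i of the negative partial log-likelihood (>= 0)."""
    f, t, d = _prepare(scores, times, events)
    shift = f.max()
    order = np.argsort(t, kind="stable")
    f_s, t_s, d_s = f[order] - shift, t[order], d[order]
    A, B, exp_f = _risk_sums(f_s, t_s, d_s)
    h_s = exp_f * A - exp_f**2 * B
    h = np.empty_like(h_s)
    h[order] = np.maximum(h_s, 0.0)
    return h
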
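"""Harrell's concordance index for right-censored risk predictions."""

from __future__ import annotations

import numpy as np


def harrell_c(risks, times, events) -> float:
    """Harrell's C-index: (#concordant + 0.5 #risk-ties) / #comparable pairs.

    A pair (i, j) with times t_i < t_j is comparable iff the earlier patient
    had the event; a pair tied in time is comparable only when exactly one of
    the two had the event (then the event patient should carry the higher
    risk). Ties in predicted risk on comparable pairs count 0.5. Raises when
    no comparable pair exists.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    n = len(r)
    if not (len(t) == len(d) == n):
        raise ValueError("length mismatch")

    # pairwise comparisons, vectorized over the upper triangle
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    ri, rj = r[:, None], r[None, :]

    earlier_event = (ti < tj) & (di == 1)           # i fails first, observed
    tied_time = (ti == tj) & (di == 1) & (dj == 0)  # event vs censored at same t
    comparable = earlier_event | tied_time

    conc = np.where(comparable & (ri > rj), 1.0, 0.0)
    conc += np.where(comparable & (ri == rj), 0.5, 0.0)

    # count each unordered pair once; comparability above is orientation-specific
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float(conc.sum() / n_comp)
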
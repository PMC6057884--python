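"""MCAR missingness injection with protected outcome columns."""

from __future__ import annotations

import numpy as np
import pandas as pd

PROTECTED = ("time", "event")


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int,
    columns: list[str] | None = None,
    protected: tuple[str, ...] = PROTECTED,
) -> pd.DataFrame:
    """Return a copy of ``table`` with cells masked completely at random.

    Outcome columns (``time``/``event`` by default) are never masked;
    explicitly requesting one of them via ``columns`` raises. ``rate`` must
    lie in [0, 1).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    if columns is not None:
        bad = [c for c in columns if c in protected]
        if bad:
            raise ValueError(f"refusing to mask protected outcome columns: {bad}")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    maskable = [c for c in (columns if columns is not None else table.columns)
                if c not in protected]
    mask = rng.random((len(table), len(maskable))) < rate
    for j, col in enumerate(maskable):
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            codes = out[col].cat.codes.to_numpy().copy()
            codes[mask[:, j]] = -1
            out[col] = pd.Categorical.from_codes(
                codes, categories=out[col].cat.categories, ordered=out[col].cat.ordered
            )
        else:
            vals = out[col].to_numpy(dtype=float).copy()
            vals[mask[:, j]] = np.nan
            out[col] = vals
    return out
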
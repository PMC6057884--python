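"""Equal-interval-width discretization into a complete categorical dataset."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class DiscreteDataset:
    """Patients x variables table of integer level codes, plus metadata.

    ``levels`` maps variable -> list of level labels; ``bin_edges`` records
    the interior cut points of discretized continuous variables. ``roles``
    tags each variable for blacklist construction. Constant columns are
    excluded (logged in ``excluded``).
    """

    data: pd.DataFrame                  # int codes
    levels: dict[str, list[str]]
    roles: dict[str, str]
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def cardinalities(self) -> dict[str, int]:
        return {c: len(self.levels[c]) for c in self.data.columns}

    def to_csv(self, path, edges_path=None) -> None:
        self.data.to_csv(path, index_label="patient_id")
        if edges_path is not None:
            with open(edges_path, "w") as fh:
                fh.write("variable\tedges\n")
                for v, e in self.bin_edges.items():
                    fh.write(v + "\t" + ",".join(f"{x:g}" for x in e) + "\n")


def discretize_equal_width(
    table: pd.DataFrame,
    roles: dict[str, str],
    n_bins: int = 3,
) -> DiscreteDataset:
    """Discretize continuous columns into ``n_bins`` equal-width intervals.

    Bin edges sit at min + k (max - min) / n_bins; intervals are left-closed
    with the last bin right-closed, so the column maximum falls in the last
    bin. Categorical columns pass through unchanged. Columns with a single
    observed level are excluded with a warning (no variance to model). The
    input must be complete (impute first).
    """
    data = {}
    levels: dict[str, list[str]] = {}
    edges: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for col in table.columns:
        s = table[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            cat = s.astype("category")
            if cat.isna().any():
                raise ValueError(f"column {col!r} contains missing values")
            observed = cat.cat.remove_unused_categories()
            if len(observed.cat.categories) < 2:
                log.warning("constant column %r excluded from the discrete dataset", col)
                excluded.append(col)
                continue
            data[col] = observed.cat.codes.astype(int)
            levels[col] = [str(x) for x in observed.cat.categories]
        else:
            v = s.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"column {col!r} contains missing values")
            if not np.isfinite(v).all():
                raise ValueError(f"column {col!r} contains non-finite values")
            lo, hi = v.min(), v.max()
            if hi == lo:
                log.warning("constant column %r excluded from the discrete dataset", col)
                excluded.append(col)
                continue
            cuts = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
            codes = np.searchsorted(cuts, v, side="right")
            codes = np.minimum(codes, n_bins - 1)
            data[col] = codes
            levels[col] = [f"bin{k}" for k in range(n_bins)]
            edges[col] = cuts
    df = pd.DataFrame(data, index=table.index)
    kept_roles = {c: roles[c] for c in df.columns}
    return DiscreteDataset(df, levels, kept_roles, edges, excluded)
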
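"""Linkage-disequilibrium utilities: pairwise r^2, window pruning, LD expansion."""

from __future__ import annotations

import numpy as np

from .matrix import GenotypeMatrix

#: sentinel for "r^2 not computable" (monomorphic overlap); treated as 0 in pruning
NOT_COMPUTABLE = float("nan")


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over joint non-missing entries.

    Returns NaN (``NOT_COMPUTABLE``) when fewer than 2 joint observations exist
    or either SNP is monomorphic on the overlap; callers treating the result as
    a pruning criterion should regard NaN as r^2 = 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 2:
        return NOT_COMPUTABLE
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return NOT_COMPUTABLE
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def _pairwise_r2(D: np.ndarray) -> np.ndarray:
    """All-pairs r^2 with missing values excluded pairwise (NaN where undefined)."""
    n, p = D.shape
    out = np.empty((p, p))
    for i in range(p):
        out[i, i] = 1.0
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = ld_r2(D[:, i], D[:, j])
    return out


def ld_prune(
    G: GenotypeMatrix, r2_max: float = 0.2, window: int = 50, step: int = 5
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of retained SNPs.

    Scanning SNPs in positional order, a candidate is dropped when any already
    retained SNP within ``window`` positions has r^2 >= ``r2_max`` with it
    (conflicts drop the later SNP). Non-computable r^2 counts as 0. ``step`` is
    accepted for interface compatibility with windowed-pass tools; the
    single-pass scan already guarantees the within-window post-condition.
    """
    D = G.dosages
    kept: list[int] = []
    for j in range(G.n_snps):
        conflict = False
        for i in reversed(kept):
            if j - i > window:
                break
            r2 = ld_r2(D[:, i], D[:, j])
            if not np.isnan(r2) and r2 >= r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(j)
    return np.array(kept, dtype=int)


def expand_ld_set(
    seed_snps: list[str], G: GenotypeMatrix, r2_min: float = 0.8
) -> list[str]:
    """Expand a seed SNP list by every panel SNP in strong LD (r^2 > r2_min) with a seed."""
    index = {s: i for i, s in enumerate(G.snp_ids)}
    unknown = [s for s in seed_snps if s not in index]
    if unknown:
        raise KeyError(f"seed SNPs not in panel: {unknown}")
    seed_idx = [index[s] for s in seed_snps]
    members = set(seed_idx)
    D = G.dosages
    for j in range(G.n_snps):
        if j in members:
            continue
        for i in seed_idx:
            r2 = ld_r2(D[:, i], D[:, j])
            if not np.isnan(r2) and r2 > r2_min:
                members.add(j)
                break
    return [G.snp_ids[j] for j in sorted(members)]
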
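"""Population-genetic summaries used to audit simulated structure."""

from __future__ import annotations

import numpy as np

from .matrix import GenotypeMatrix


def hudson_fst(G: GenotypeMatrix, labels: np.ndarray) -> float:
    """Hudson's FST estimator between two subpopulations (ratio of averages).

    Per SNP, numerator (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    denominator p1(1-p2) + p2(1-p1), both averaged over SNPs before taking the
    ratio -- the ratio-of-averages form recommended for genome-wide estimates.
    ``labels`` must contain exactly two distinct values.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("hudson_fst requires exactly two subpopulations")
    D = G.dosages
    num_parts = []
    den_parts = []
    masks = [labels == g for g in groups]
    p_hat = []
    n_eff = []
    for m in masks:
        sub = D[m]
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_hat.append(np.nansum(sub, axis=0) / (2.0 * np.maximum(cnt, 1)))
        n_eff.append(2.0 * cnt)  # allele counts
    p1, p2 = p_hat
    n1, n2 = n_eff
    ok = (n1 > 2) & (n2 > 2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        raise ValueError("no informative SNPs for FST")
    return float(num[keep].mean() / den[keep].mean())
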
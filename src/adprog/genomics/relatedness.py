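"""Pairwise relatedness (method-of-moments IBD) and SNP-based inbreeding.

The kinship estimator follows the PLINK method of moments for
identity-by-descent: genome-wide identity-by-state (IBS) counts are combined
with their allele-frequency expectations under IBD states 0/1/2 to solve for
P(IBD=0), P(IBD=1), P(IBD=2); PI-HAT = P(IBD=2) + P(IBD=1)/2.

The inbreeding coefficient uses the SNP-based moment estimator

    F = sum_j [x_j^2 - (1 + 2 p_j) x_j + 2 p_j^2] / sum_j [2 p_j (1 - p_j)]

over SNPs observed in the individual, with x the minor-allele dosage and p the
sample minor-allele frequency (monomorphic SNPs excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)

MIN_OVERLAP = 100  # pairs with fewer jointly observed SNPs are flagged unreliable


@dataclass
class RelatednessReport:
    patient_ids: list[str]
    pihat: np.ndarray                     # symmetric, self-pairs = 1
    inbreeding: np.ndarray                # per-individual F
    unreliable_pairs: list[tuple[str, str]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _ibs_state_expectations(p: np.ndarray) -> dict[str, np.ndarray]:
    """Per-SNP P(IBS=s | IBD=z) under Hardy-Weinberg with minor freq p."""
    q = 1.0 - p
    return {
        "e00": 2 * p**2 * q**2,                     # IBS0 | IBD0
        "e10": 4 * p**3 * q + 4 * p * q**3,          # IBS1 | IBD0
        "e20": p**4 + q**4 + 4 * p**2 * q**2,        # IBS2 | IBD0
        "e11": 2 * p**2 * q + 2 * p * q**2,          # IBS1 | IBD1
        "e21": p**3 + q**3 + p**2 * q + p * q**2,    # IBS2 | IBD1
    }


def kinship_mom(G: GenotypeMatrix) -> RelatednessReport:
    """Pairwise PI-HAT for all patient pairs (vectorized over indicator matrices).

    Per pair, IBS counts and the corresponding expectation sums are restricted
    to SNPs non-missing in both individuals; PI-HAT is truncated into [0, 1].
    """
    D = G.dosages
    obs = (~np.isnan(D)).astype(float)
    p = G.maf()
    poly = np.nan_to_num(p, nan=0.0)
    usable = (poly > 0) & (poly < 1)
    D = np.nan_to_num(D[:, usable], nan=-9.0)
    obs = obs[:, usable]
    p = poly[usable]
    A0 = ((D == 0)).astype(float)
    A1 = ((D == 1)).astype(float)
    A2 = ((D == 2)).astype(float)

    # observed IBS counts per pair
    ibs0 = A0 @ A2.T + A2 @ A0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    n_obs = obs @ obs.T
    ibs1 = n_obs - ibs0 - ibs2

    e = _ibs_state_expectations(p)
    # per-pair expectation sums over the jointly observed SNPs
    def pairsum(w: np.ndarray) -> np.ndarray:
        return (obs * w) @ obs.T

    s00 = pairsum(e["e00"])
    s10 = pairsum(e["e10"])
    s20 = pairsum(e["e20"])
    s11 = pairsum(e["e11"])
    s21 = pairsum(e["e21"])

    # raw (unclipped) moment solutions; clipping the components individually
    # before combining would correlate their sampling errors and bias PI-HAT
    # upward on modest panels, so only the final PI-HAT is truncated
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(s00 > 0, ibs0 / s00, 0.0)
        p1 = np.where(s11 > 0, (ibs1 - p0 * s10) / s11, 0.0)
        p2 = np.where(n_obs > 0, (ibs2 - p0 * s20 - p1 * s21) / n_obs, 0.0)
    pihat = np.clip(p2 + 0.5 * p1, 0.0, 1.0)
    pihat = 0.5 * (pihat + pihat.T)
    np.fill_diagonal(pihat, 1.0)

    unreliable = []
    ii, jj = np.where(np.triu(n_obs < MIN_OVERLAP, k=1))
    for i, j in zip(ii, jj):
        unreliable.append((G.patient_ids[i], G.patient_ids[j]))
    if unreliable:
        log.warning("%d pairs have <%d overlapping SNPs", len(unreliable), MIN_OVERLAP)
    return RelatednessReport(
        patient_ids=list(G.patient_ids),
        pihat=pihat,
        inbreeding=inbreeding_coeff(G),
        unreliable_pairs=unreliable,
    )


def inbreeding_coeff(G: GenotypeMatrix) -> np.ndarray:
    """Per-individual SNP-based moment estimator of F (see module docstring)."""
    p = G.maf()
    poly = np.nan_to_num(p, nan=0.0)
    usable = (poly > 0) & (poly < 1)
    if not usable.any():
        raise ValueError("no polymorphic SNPs available for inbreeding estimation")
    X = G.dosages[:, usable]
    p = poly[usable]
    obs = ~np.isnan(X)
    Xf = np.nan_to_num(X, nan=0.0)
    num_terms = Xf**2 - (1.0 + 2.0 * p) * Xf + 2.0 * p**2
    num = np.where(obs, num_terms, 0.0).sum(axis=1)
    den = (obs * (2.0 * p * (1.0 - p))).sum(axis=1)
    if np.any(den <= 0):
        raise ValueError("individual with no observed polymorphic SNPs")
    return num / den


def relatedness_filter(
    report: RelatednessReport,
    kinship_thresh: float = 0.1,
    inbreeding_thresh: float = 0.1,
    missing_counts: np.ndarray | None = None,
) -> list[str]:
    """Return patient ids surviving the relatedness / inbreeding filter.

    Individuals with |F| above ``inbreeding_thresh`` are dropped. Related pairs
    (PI-HAT above ``kinship_thresh``) are then resolved greedily by descending
    PI-HAT, dropping one member per pair: the one with more missing genotypes,
    then the lexicographically larger id. The report's ``kept``/``dropped``
    lists are filled in place.
    """
    ids = report.patient_ids
    n = len(ids)
    dropped: set[int] = set(np.where(np.abs(report.inbreeding) > inbreeding_thresh)[0])
    miss = np.zeros(n) if missing_counts is None else np.asarray(missing_counts)

    iu, ju = np.triu_indices(n, k=1)
    vals = report.pihat[iu, ju]
    order = np.argsort(-vals, kind="stable")
    for k in order:
        if vals[k] <= kinship_thresh:
            break
        i, j = int(iu[k]), int(ju[k])
        if i in dropped or j in dropped:
            continue
        if miss[i] != miss[j]:
            dropped.add(i if miss[i] > miss[j] else j)
        else:
            dropped.add(i if ids[i] > ids[j] else j)
    kept = [ids[i] for i in range(n) if i not in dropped]
    report.kept = kept
    report.dropped = [ids[i] for i in sorted(dropped)]
    return kept
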
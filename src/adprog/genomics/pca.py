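"""Principal components of the standardized genotype matrix.

Genotypes are standardized SNP-wise to (x - 2p) / sqrt(2p(1-p)) with missing
calls mean-imputed (zero after centering). Patient-space eigenvectors (EV1,
EV2, ...) are returned as features describing global population structure.
Small panels use a dense SVD; large panels an iterative Lanczos solver. A
probabilistic-PCA EM variant is available behind ``method="ppca"`` as a
regularized alternative for panels with many more SNPs than patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

from .matrix import GenotypeMatrix

_DENSE_LIMIT = 2_000_000  # n*p below which the dense SVD path is used


@dataclass
class PCAResult:
    eigenvectors: np.ndarray      # (n_patients, k), orthonormal columns
    eigenvalues: np.ndarray       # nonincreasing
    explained_variance: np.ndarray  # fractions in (0, 1]
    loadings: np.ndarray          # (n_snps, k) SNP-space directions
    singular_values: np.ndarray


def standardize_genotypes(G: GenotypeMatrix) -> np.ndarray:
    p = np.nan_to_num(G.maf(), nan=0.0)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    scale[scale == 0] = 1.0
    Z = (np.nan_to_num(G.dosages, nan=0.0) - 2.0 * p) / scale
    Z[np.isnan(G.dosages)] = 0.0
    # re-center columns so mean-imputation leaves them exactly centered
    Z -= Z.mean(axis=0)
    return Z


def pca_top_k(G: GenotypeMatrix, k: int = 32, method: str = "svd") -> PCAResult:
    """Top-k principal components of the standardized genotype matrix.

    ``k`` must satisfy k <= min(n_patients - 1, n_snps). ``method`` is "svd"
    (dense or Lanczos depending on panel size) or "ppca" (EM for probabilistic
    PCA, then orthonormalized).
    """
    n, p = G.n_patients, G.n_snps
    kmax = min(n - 1, p)
    if k > kmax:
        raise ValueError(f"k={k} exceeds min(n_patients - 1, n_snps) = {kmax}")
    Z = standardize_genotypes(G)
    total_var = (Z**2).sum() / max(n - 1, 1)

    if method == "ppca":
        W = _ppca_em(Z, k)
        # orthonormal patient-space basis from the fitted subspace
        U, s, Vt = np.linalg.svd(Z @ W, full_matrices=False)
        U = U[:, :k]
        proj = U.T @ Z
        sv = np.linalg.norm(proj, axis=1)
        order = np.argsort(-sv)
        U, sv = U[:, order], sv[order]
        V = (Z.T @ U) / np.where(sv > 0, sv, 1.0)
    elif n * p <= _DENSE_LIMIT or k >= kmax - 1:
        U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
        U, sv, V = U[:, :k], sv[:k], Vt[:k].T
    else:
        U, sv, Vt = svds(Z, k=k)  # Lanczos-type iterative solver
        order = np.argsort(-sv)
        U, sv, V = U[:, order], sv[order], Vt[order].T
    # deterministic sign convention: largest-|.| loading positive
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    eigvals = sv**2 / max(n - 1, 1)
    frac = eigvals / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(U, eigvals, frac, V, sv)


def _ppca_em(Z: np.ndarray, k: int, n_iter: int = 50, tol: float = 1e-6) -> np.ndarray:
    """EM for probabilistic PCA (isotropic noise); returns the p x k weight matrix."""
    rng = np.random.default_rng(0)
    n, p = Z.shape
    W = rng.standard_normal((p, k)) * 0.01
    sigma2 = 1.0
    ZtZ_tr = (Z**2).sum()
    prev = np.inf
    for _ in range(n_iter):
        M = W.T @ W + sigma2 * np.eye(k)
        Minv = np.linalg.inv(M)
        # E-step sufficient statistics
        EX = Z @ W @ Minv                        # n x k
        sumXX = n * sigma2 * Minv + EX.T @ EX
        # M-step
        ZtEX = Z.T @ EX
        W_new = ZtEX @ np.linalg.inv(sumXX)
        sigma2 = (ZtZ_tr - 2 * (ZtEX * W_new).sum() + np.trace(sumXX @ (W_new.T @ W_new))) / (n * p)
        sigma2 = max(sigma2, 1e-12)
        delta = np.abs(W_new - W).max()
        W = W_new
        if delta < tol or abs(prev - delta) < tol * 1e-2:
            break
        prev = delta
    return W
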
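"""Reference-panel LD: standardization, block LD matrices, eigendecomposition,
z-score decorrelation and LD scores.

The LD matrix of a block, V = X'X / n on column-standardized genotypes X,
is eigendecomposed as V = U diag(w) U'. Rotating a block's z-score vector
by U' yields components that are independent under the model, which is
what makes the per-block weighted regressions of the local estimator
valid. Because the panel has n samples, rank(V) <= n and only the leading
spectrum is informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class EigenSystem:
    """Eigenvalues (descending, clipped at 0) and eigenvectors of a block
    LD matrix, with the usable numerical rank."""

    w: np.ndarray        # (m_i,) nonincreasing, >= 0
    U: np.ndarray        # (m_i, m_i) orthonormal columns
    m: int
    rank: int            # count of eigenvalues > rel_tol * w_max

    def __post_init__(self):
        self.m = int(self.m)
        self.rank = int(self.rank)


def standardize_genotypes(raw: np.ndarray, return_index: bool = False):
    """Column-standardize a dosage matrix (mean 0, variance 1).

    Missing entries (NaN) are mean-imputed per SNP before centering.
    Monomorphic (zero-variance) columns are removed; their indices are
    returned when ``return_index`` so callers can keep SNP metadata in
    sync.
    """
    X = np.array(raw, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (samples x SNPs)")
    mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])
    X -= mean
    sd = X.std(axis=0)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("standardize_genotypes: removed %d monomorphic columns", n_drop)
    if not keep.any():
        raise ValueError("no polymorphic SNPs in block")
    X = X[:, keep] / sd[keep]
    if return_index:
        return X, np.flatnonzero(keep)
    return X


def estimate_ld(X: np.ndarray) -> np.ndarray:
    """Sample LD matrix V = X'X / n of a standardized block (unit diagonal)."""
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 panel samples to estimate LD")
    return (X.T @ X) / n


def eigendecompose(V: np.ndarray, rel_tol: float = 1e-8) -> EigenSystem:
    """Eigendecompose a symmetric LD matrix, descending order, w clipped at 0."""
    V = np.asarray(V, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("LD matrix is not symmetric")
    w, U = np.linalg.eigh(V)
    w, U = w[::-1].copy(), U[:, ::-1].copy()
    w = np.clip(w, 0.0, None)
    rank = int(np.sum(w > rel_tol * w[0])) if w.size and w[0] > 0 else 0
    return EigenSystem(w=w, U=U, m=V.shape[0], rank=rank)


def transform_z(z: np.ndarray, eig: EigenSystem) -> np.ndarray:
    """Decorrelate a block's z scores: z~ = U' z (an isometry)."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != eig.m:
        raise ValueError(f"z has length {z.shape[0]}, block has {eig.m} SNPs")
    return eig.U.T @ z


def compute_ld_scores(X: np.ndarray, pos: np.ndarray, chrom: np.ndarray,
                      window_bp: int = 1_000_000) -> np.ndarray:
    """Per-SNP LD scores from a standardized panel.

    ld_score(j) = sum over SNPs k on the same chromosome with
    |pos_k - pos_j| <= window_bp of r2_adj(j, k), where
    r2_adj = r^2 - (1 - r^2)/(n - 2) is the usual unbiased small-sample
    adjustment. Includes the self term (~1).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need >= 3 panel samples for adjusted LD scores")
    pos = np.asarray(pos)
    chrom = np.asarray(chrom)
    scores = np.empty(m)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        r = (X[:, idx].T @ X[:, idx]) / n
        r2 = r ** 2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        p = pos[idx].astype(float)
        in_window = np.abs(p[:, None] - p[None, :]) <= window_bp
        scores[idx] = np.where(in_window, r2_adj, 0.0).sum(axis=1)
    return scores
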
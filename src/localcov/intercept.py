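"""Cross-trait LD score regression intercept.

When two GWAS share n_s samples whose non-genetic effects are correlated,
the per-SNP products z1_j * z2_j acquire a constant offset
a = n_s * rho_t / sqrt(n1 * n2), where rho_t is the total (genetic plus
non-genetic) covariance of the traits on shared individuals. Regressing
z1_j * z2_j on sqrt(n1*n2) * ldscore_j / m genome-wide, with a free
intercept, separates that offset (the intercept a_hat) from the polygenic
signal (the slope, a genome-wide covariance estimate on the LDSC scale).

Weighting is two-step: a first pass of the univariate regressions
z_t^2 ~ n_t * ldscore / m yields crude per-trait polygenicity slopes
c_t = n_t * h2_t / m, and the cross-trait pass then uses reciprocal
approximate-variance weights 1 / [max(l, 1) * (1 + c1 l)(1 + c2 l)] —
the product-variance profile implied by the model. The intercept's
sampling variance comes from a delete-one block jackknife over contiguous
SNP blocks sized to exceed the LD correlation length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CrossTraitIntercept:
    """Estimated sample-overlap nuisance a = n_s rho_t / sqrt(n1 n2)."""

    a_hat: float
    var_a: float
    slope: float
    n_blocks: int


def _wls_line(sw, swx, swx2, swy, swxy):
    """Closed-form weighted least squares for y ~ intercept + slope * x.

    Inputs are the weighted sufficient statistics Sum(w), Sum(w x),
    Sum(w x^2), Sum(w y), Sum(w x y); supports vectorized (array) inputs.
    """
    denom = sw * swx2 - swx ** 2
    intercept = (swx2 * swy - swx * swxy) / denom
    slope = (sw * swxy - swx * swy) / denom
    return intercept, slope


def _fit(y, x, w):
    return _wls_line(w.sum(), (w * x).sum(), (w * x * x).sum(),
                     (w * y).sum(), (w * x * y).sum())


def _polygenicity_slope(z, n, ld_scores, m) -> float:
    """Crude c = n h2 / m from the univariate regression z^2 ~ n l / m."""
    x = n * ld_scores / m
    w = 1.0 / np.maximum(ld_scores, 1.0)
    _, slope = _fit(z ** 2, x, w)
    return max(float(slope), 0.0) * n / m


def _design(z1, z2, n1, n2, ld_scores, m, weights):
    y = z1 * z2
    x = np.sqrt(float(n1) * n2) * ld_scores / m
    if np.ptp(x) < 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError(
            "LD scores are (numerically) constant: the intercept and slope "
            "are not separable; supply scores with a window covering "
            "neighbouring SNPs")
    if weights == "ldsc":
        c1 = _polygenicity_slope(z1, n1, ld_scores, m)
        c2 = _polygenicity_slope(z2, n2, ld_scores, m)
        w = 1.0 / (np.maximum(ld_scores, 1.0)
                   * (1.0 + c1 * ld_scores) * (1.0 + c2 * ld_scores))
    elif weights in (None, "none"):
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")
    return y, x, w


def _auto_blocks(n_snps: int) -> int:
    # jackknife blocks must span more than the LD correlation length;
    # aim for ~200 SNPs per block, between 8 and the LDSC-style 200 blocks
    return int(min(200, max(8, n_snps // 200)))


def grouped_edges(block_starts, n_snps: int, max_blocks: int = 200):
    """Jackknife block start indices aligned to LD-block boundaries.

    Groups the partition's blocks into at most ``max_blocks`` contiguous
    jackknife blocks, so that no jackknife boundary cuts through an LD
    block (a cut boundary leaves correlation between adjacent jackknife
    blocks and deflates the variance estimate).
    """
    starts = np.unique(np.asarray(block_starts, dtype=int))
    if starts.size == 0 or starts[0] != 0:
        starts = np.concatenate([[0], starts])
    n_groups = min(max_blocks, starts.size)
    pick = np.linspace(0, starts.size, n_groups, endpoint=False).astype(int)
    return starts[np.unique(pick)]


def cross_trait_regression(z1, z2, n1, n2, ld_scores, m=None,
                           weights: str = "ldsc",
                           n_jackknife_blocks: int | str = "auto",
                           jackknife_edges=None) -> CrossTraitIntercept:
    """Estimate the overlap nuisance a_hat and its jackknife variance.

    Parameters
    ----------
    z1, z2 : aligned genome-wide z-score vectors (genome position order).
    n1, n2 : study sample sizes.
    ld_scores : per-SNP LD scores on the same SNP order.
    m : SNP count used to scale the regressor (defaults to len(z1)).
    weights : 'ldsc' for the two-step reciprocal-variance weights,
        'none' for ordinary least squares.
    n_jackknife_blocks : block count, or 'auto' to target ~200 SNPs per
        block (at most 200 blocks). Ignored when ``jackknife_edges`` is
        given.
    jackknife_edges : optional start indices of jackknife blocks, e.g.
        from :func:`grouped_edges` so blocks respect LD boundaries.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    if m is None:
        m = z1.size
    if z1.size < 200:
        raise ValueError(
            f"only {z1.size} SNPs; need >= 200 genome-wide for a stable "
            "intercept")
    y, x, w = _design(z1, z2, n1, n2, np.asarray(ld_scores, float), m, weights)
    a_hat, slope = _fit(y, x, w)
    if jackknife_edges is not None:
        edges = np.asarray(jackknife_edges, dtype=int)
    else:
        if n_jackknife_blocks == "auto":
            n_jackknife_blocks = _auto_blocks(z1.size)
        edges = np.linspace(0, z1.size, int(n_jackknife_blocks),
                            endpoint=False).astype(int)
    var_a = _jackknife_from_design(y, x, w, edges)
    return CrossTraitIntercept(a_hat=float(a_hat), var_a=float(var_a),
                               slope=float(slope), n_blocks=len(edges))


def _jackknife_from_design(y, x, w, edges) -> float:
    n_blocks = len(edges)
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if y.size < n_blocks:
        raise ValueError(
            f"{y.size} SNPs cannot fill {n_blocks} jackknife blocks")
    stats = np.stack([w, w * x, w * x * x, w * y, w * x * y])
    block = np.add.reduceat(stats, edges, axis=1)  # (5, B)
    total = stats.sum(axis=1, keepdims=True)
    a_loo, _ = _wls_line(*(total - block))
    a_bar = a_loo.mean()
    return float((n_blocks - 1) / n_blocks * ((a_loo - a_bar) ** 2).sum())


def jackknife_variance(z1, z2, n1, n2, ld_scores, m=None,
                       weights: str = "ldsc",
                       n_blocks: int | str = "auto") -> float:
    """Delete-one-block jackknife variance of the intercept.

    SNPs are cut into ``n_blocks`` contiguous blocks (genome order); the
    intercept is refitted with each block removed and the variance is
    (B-1)/B * sum((a_b - mean a_b)^2). Blocks must be wider than the LD
    correlation length for the estimate to be honest.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    if m is None:
        m = z1.size
    if n_blocks == "auto":
        n_blocks = _auto_blocks(z1.size)
    y, x, w = _design(z1, z2, n1, n2, np.asarray(ld_scores, float), m, weights)
    edges = np.linspace(0, z1.size, int(n_blocks), endpoint=False).astype(int)
    return _jackknife_from_design(y, x, w, edges)
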
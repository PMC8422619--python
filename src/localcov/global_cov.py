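"""Genome-wide genetic covariance as the block-diagonal special case.

With approximately independent LD blocks, the genome-wide LD matrix is
block diagonal, so the whole genome can be treated as one region whose
eigensystem is the union of the per-block eigensystems. The global
estimate pools every block's retained components (at each block's
selected rank) into a single no-intercept weighted regression of the
overlap-corrected products on squared eigenvalues, with weights built
from genome-wide heritabilities aggregated from the per-block
method-of-moments estimates.

The sum of the per-block local estimates should closely track the global
estimate; ``sum_local_vs_global`` reports that concordance diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .local import wald_test_t


@dataclass
class BlockWork:
    """Per-block intermediates retained for the pooled global fit."""

    w: np.ndarray        # eigenvalues, descending, length >= k
    eta: np.ndarray      # overlap-corrected products, same order
    k: int               # selected rank
    m: int
    h2_1_raw: float
    h2_2_raw: float


@dataclass
class GlobalCovarianceEstimate:
    rho: float
    var_conditional: float
    var_intercept_prop: float
    var: float
    p_value: float
    h2_1: float
    h2_2: float
    corr: float | None
    k_total: int
    m_total: int


def global_cov(blocks: list[BlockWork], n1: int, n2: int, var_a: float,
               var_a_df: int | None = None) -> GlobalCovarianceEstimate:
    """Pooled genome-wide covariance from the per-block retained components."""
    blocks = [b for b in blocks if b.k >= 1]
    if not blocks:
        raise ValueError("no estimable blocks: cannot form a global estimate")
    m_total = sum(b.m for b in blocks)
    k_total = sum(b.k for b in blocks)
    h2_1 = sum(max(b.h2_1_raw, 0.0) for b in blocks)
    h2_2 = sum(max(b.h2_2_raw, 0.0) for b in blocks)

    c1 = n1 * h2_1 / m_total
    c2 = n2 * h2_2 / m_total
    s4 = se = see = s3 = 0.0
    for b in blocks:
        w = np.asarray(b.w, float)[:b.k]
        eta = np.asarray(b.eta, float)[:b.k]
        q2 = (c1 * w ** 2 + w) * (c2 * w ** 2 + w)
        s4 += (w ** 4 / q2).sum()
        s3 += (w ** 3 / q2).sum()
        se += (eta * w ** 2 / q2).sum()
        see += (eta ** 2 / q2).sum()

    scale = m_total ** 2 / (float(n1) * n2)
    rho = m_total / np.sqrt(float(n1) * n2) * se / s4
    theo = scale / s4
    if k_total >= 3:
        var_cond = theo * max(see - se ** 2 / s4, 0.0) / (k_total - 1)
    else:
        var_cond = theo
    var_prop = scale * (s3 / s4) ** 2 * var_a
    var = var_cond + var_prop
    # same analytic-floor guard as the per-block test
    p = wald_test_t(rho, max(var_cond, theo), var_prop, k_total, var_a_df) \
        if var > 0 else np.nan
    corr = rho / np.sqrt(h2_1 * h2_2) if h2_1 > 0 and h2_2 > 0 else None

    return GlobalCovarianceEstimate(
        rho=float(rho), var_conditional=float(var_cond),
        var_intercept_prop=float(var_prop), var=float(var), p_value=p,
        h2_1=float(h2_1), h2_2=float(h2_2), corr=corr,
        k_total=k_total, m_total=m_total)


def sum_local_vs_global(local_sums, global_rhos) -> dict:
    """Concordance between summed local estimates and global estimates.

    Accepts scalars (one trait pair) or equal-length sequences (several
    pairs / replicates). Returns the sums, the paired differences, and —
    when at least two pairs are given — the squared Pearson correlation.
    """
    s = np.atleast_1d(np.asarray(local_sums, float))
    g = np.atleast_1d(np.asarray(global_rhos, float))
    if s.shape != g.shape:
        raise ValueError("local sums and global estimates differ in length")
    out = {"sum_local": s, "global": g, "difference": s - g, "r2": None}
    if s.size >= 2 and np.std(s) > 0 and np.std(g) > 0:
        out["r2"] = float(np.corrcoef(s, g)[0, 1] ** 2)
    return out
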
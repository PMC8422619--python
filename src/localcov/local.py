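"""Local genetic covariance estimation in a single LD block.

Model. With z~ the block's decorrelated z scores (z~ = U'z for the
reference eigensystem V = U diag(w) U'), the per-component products obey

    E[z~_1j z~_2j]   = sqrt(n1 n2) rho_i / m_i * w_j^2  +  a * w_j
    Var[z~_1j z~_2j] ~ q_j^2
    q_j^2 = (n1 h2_1i / m_i * w_j^2 + w_j) (n2 h2_2i / m_i * w_j^2 + w_j)

where rho_i is the block's genetic covariance, h2_ti its per-trait
heritabilities, and a = n_s rho_t / sqrt(n1 n2) the sample-overlap
nuisance estimated genome-wide (cross-trait LDSC intercept). Subtracting
a_hat * w_j gives the corrected products eta_j, and rho_i is the
no-intercept weighted least squares slope of eta on w^2 (weights 1/q^2),
rescaled by m_i / sqrt(n1 n2).

Because the reference panel has limited sample size, only the leading K_i
eigencomponents are used. K_i is chosen adaptively: for each candidate K
the theoretical (information-based) and empirical (residual-based)
variances of rho_hat are computed, and K_i minimizes the larger of the
two — small K wastes information (high theoretical variance), large K
admits noise-dominated components (exploding empirical variance).

The total variance adds the propagated uncertainty of a_hat (law of total
variance), and a two-sided normal reference gives the p value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

#: smallest candidate rank for the adaptive search
DEFAULT_K_MIN = 10


@dataclass
class LocalCovarianceEstimate:
    """Per-block estimate of local genetic covariance and its uncertainty."""

    block: int
    rho: float
    var_conditional: float      # residual-based variance at the selected K
    var_intercept_prop: float   # propagated Var(a_hat)
    var_total: float
    k: int
    m: int
    h2_1: float                 # raw (possibly negative) local heritabilities
    h2_2: float
    p_value: float
    corr: float | None = None
    corr_se: float | None = None
    status: str = "estimated"


@dataclass
class LiabilityScaleParams:
    """Case-control scale parameters for one study pair.

    For each study: sample prevalence P (cases/total in the GWAS) and
    population prevalence K of the disorder. The liability threshold is
    tau = Phi^-1(1 - K).
    """

    sample_prev1: float
    pop_prev1: float
    sample_prev2: float
    pop_prev2: float

    def __post_init__(self):
        for v in (self.sample_prev1, self.pop_prev1,
                  self.sample_prev2, self.pop_prev2):
            if not 0.0 < v < 1.0:
                raise ValueError(f"prevalence {v} outside (0, 1)")

    @property
    def tau1(self) -> float:
        return stats.norm.isf(self.pop_prev1)

    @property
    def tau2(self) -> float:
        return stats.norm.isf(self.pop_prev2)


# ---------------------------------------------------------------------------
# elementary estimator pieces


def local_h2_mom(z_t: np.ndarray, w: np.ndarray, n: int, m: int,
                 k: int) -> float:
    """Method-of-moments local heritability from the leading k components.

    Matches E[z~_j^2] = n h2 / m * w_j^2 + w_j summed over j <= k:

        h2_hat = m * (sum z~_j^2 / w_j - k) / (n * sum w_j)

    Returns the raw value, which may be negative; callers clip at 0
    before building regression weights.
    """
    z_t = np.asarray(z_t, float)[:k]
    w = np.asarray(w, float)[:k]
    if np.any(w <= 0):
        raise ValueError("zero eigenvalue inside the leading-k prefix")
    return float(m * ((z_t ** 2 / w).sum() - k) / (n * w.sum()))


def compute_weights(w, h2_1, h2_2, n1, n2, m) -> np.ndarray:
    """Per-component variance proxy q_j^2 (reciprocal regression weights)."""
    w = np.asarray(w, float)
    h2_1 = max(float(h2_1), 0.0)
    h2_2 = max(float(h2_2), 0.0)
    return ((n1 * h2_1 / m * w ** 2 + w)
            * (n2 * h2_2 / m * w ** 2 + w))


def compute_eta(z1_t, z2_t, w, a_hat: float) -> np.ndarray:
    """Overlap-corrected component products eta_j = z~_1j z~_2j - a_hat w_j."""
    return np.asarray(z1_t, float) * np.asarray(z2_t, float) \
        - a_hat * np.asarray(w, float)


def wls_rho(eta, w, q2, k: int, n1, n2, m) -> float:
    """No-intercept WLS slope of eta on w^2 (weights 1/q^2), rescaled.

    rho_hat = m / sqrt(n1 n2) * sum(eta w^2 / q^2) / sum(w^4 / q^2)
    over the leading k components.
    """
    eta = np.asarray(eta, float)[:k]
    w = np.asarray(w, float)[:k]
    q2 = np.asarray(q2, float)[:k]
    denom = (w ** 4 / q2).sum()
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate eigen spectrum: sum w^4/q^2 is not positive")
    return float(m / np.sqrt(float(n1) * n2) * (eta * w ** 2 / q2).sum() / denom)


def theoretical_var(w, q2, k: int, n1, n2, m) -> float:
    """Information-based variance of rho_hat given a_hat:
    (m^2 / (n1 n2)) / sum_{j<=k} w_j^4 / q_j^2."""
    w = np.asarray(w, float)[:k]
    q2 = np.asarray(q2, float)[:k]
    return float(m ** 2 / (float(n1) * n2) / (w ** 4 / q2).sum())


def empirical_var(eta, w, q2, k: int, n1, n2, m) -> float:
    """Residual-based variance of rho_hat given a_hat.

    theoretical_var times the weighted residual sum of squares of the
    no-intercept fit, divided by (k - 1). Nonnegative by Cauchy-Schwarz;
    exactly 0 when eta is proportional to w^2.
    """
    eta = np.asarray(eta, float)[:k]
    w = np.asarray(w, float)[:k]
    q2 = np.asarray(q2, float)[:k]
    s4 = (w ** 4 / q2).sum()
    resid = (eta ** 2 / q2).sum() - (eta * w ** 2 / q2).sum() ** 2 / s4
    resid = max(resid, 0.0)  # guard tiny negative round-off
    return float(m ** 2 / (float(n1) * n2) / s4 * resid / (k - 1))


def intercept_var_propagation(w, q2, k: int, n1, n2, m, var_a: float) -> float:
    """Variance in rho_hat induced by the uncertainty of a_hat:
    (m^2/(n1 n2)) * (sum w^3/q^2 / sum w^4/q^2)^2 * var_a."""
    w = np.asarray(w, float)[:k]
    q2 = np.asarray(q2, float)[:k]
    s4 = (w ** 4 / q2).sum()
    s3 = (w ** 3 / q2).sum()
    return float(m ** 2 / (float(n1) * n2) * (s3 / s4) ** 2 * var_a)


def total_var(var_conditional: float, var_intercept_prop: float) -> float:
    """Law of total variance: residual-based plus propagated components."""
    return var_conditional + var_intercept_prop


def wald_test(rho_hat: float, var: float) -> float:
    """Two-sided normal p value for rho_hat / sqrt(var)."""
    if var <= 0:
        raise ValueError("non-positive variance: p value undefined")
    return float(2.0 * stats.norm.sf(abs(rho_hat) / np.sqrt(var)))


def wald_test_t(rho_hat: float, var_conditional: float,
                var_intercept_prop: float, k: int,
                var_a_df: int | None) -> float:
    """Two-sided p value acknowledging the variance estimate's precision.

    The residual-based component carries k - 1 degrees of freedom and the
    propagated-intercept component carries the jackknife's block count
    minus one; the Welch-Satterthwaite combination gives the effective
    degrees of freedom of a t reference. With genome-scale inputs both
    counts are large and this is indistinguishable from the normal
    reference; at small block counts the normal is anti-conservative.
    Falls back to the normal reference when no jackknife df is available.
    """
    var = var_conditional + var_intercept_prop
    if var <= 0:
        raise ValueError("non-positive variance: p value undefined")
    stat = abs(rho_hat) / np.sqrt(var)
    if var_a_df is None or var_a_df < 1 or var_intercept_prop <= 0:
        if k < 2:
            return float(2.0 * stats.norm.sf(stat))
        df = k - 1
    else:
        df = var ** 2 / (var_conditional ** 2 / max(k - 1, 1)
                         + var_intercept_prop ** 2 / var_a_df)
    return float(2.0 * stats.t.sf(stat, df))


def local_h2_var(w, q_t, n: int, m: int, k: int) -> float:
    """Sampling variance of the method-of-moments local heritability.

    Each z~_j is mean-zero normal with variance v_j = n h2/m w_j^2 + w_j
    (one factor of q_j^2), so Var(z~_j^2) = 2 v_j^2 and

        Var(h2_hat) = (m / (n sum w))^2 * sum 2 v_j^2 / w_j^2.
    """
    w = np.asarray(w, float)[:k]
    v = np.asarray(q_t, float)[:k]
    return float((m / (n * w.sum())) ** 2 * (2.0 * v ** 2 / w ** 2).sum())


def local_correlation(rho_hat, var_rho, h2_1, h2_2, var_h2_1, var_h2_2):
    """Local genetic correlation rho / sqrt(h2_1 h2_2) with a delta-method SE.

    Returns (corr, se), or (None, None) when either heritability estimate
    is non-positive (the ratio is then numerically unstable and reported
    as undefined). The SE treats the three estimates as independent.
    """
    if h2_1 <= 0 or h2_2 <= 0:
        return None, None
    corr = rho_hat / np.sqrt(h2_1 * h2_2)
    rel2 = 0.0
    if rho_hat != 0:
        rel2 += var_rho / rho_hat ** 2
        rel2 += var_h2_1 / (4.0 * h2_1 ** 2) + var_h2_2 / (4.0 * h2_2 ** 2)
        se = abs(corr) * np.sqrt(rel2)
    else:
        se = np.sqrt(var_rho / (h2_1 * h2_2))
    return float(corr), float(se)


# ---------------------------------------------------------------------------
# adaptive rank selection


def _candidate_grid(rank: int, k_min: int, k_max: int | None):
    upper = rank if k_max is None else min(rank, k_max)
    if upper < 1:
        return None
    if upper < k_min:
        # tiny or rank-deficient block: no search, use everything available
        return np.array([upper])
    return np.arange(k_min, upper + 1)


def select_k(z1_t, z2_t, w, n1, n2, m, a_hat,
             k_min: int = DEFAULT_K_MIN, k_max: int | None = None):
    """Evaluate v(K) = max(theoretical, empirical variance) over the
    candidate grid and return (k_star, grid, v).

    Heritabilities (and hence the weights q^2) are re-estimated at every
    candidate K from the truncated spectrum. Ties in argmin v break to
    the smallest K.
    """
    z1_t = np.asarray(z1_t, float)
    z2_t = np.asarray(z2_t, float)
    w = np.asarray(w, float)
    rank = int(np.sum(w > 0))
    grid = _candidate_grid(rank, k_min, k_max)
    if grid is None:
        return None, None, None
    upper = grid[-1]
    wu = w[:upper]

    # prefix-sum h2 estimates for every K in one pass
    ks = np.arange(1, upper + 1)
    cz1 = np.cumsum(z1_t[:upper] ** 2 / wu)
    cz2 = np.cumsum(z2_t[:upper] ** 2 / wu)
    cw = np.cumsum(wu)
    h2_1 = np.clip(m * (cz1 - ks) / (n1 * cw), 0.0, None)[grid - 1]
    h2_2 = np.clip(m * (cz2 - ks) / (n2 * cw), 0.0, None)[grid - 1]

    eta = z1_t[:upper] * z2_t[:upper] - a_hat * wu
    w2, w4 = wu ** 2, wu ** 4
    # q^2 depends on K through the re-estimated h2's: build the (K, j) grid
    q2 = ((n1 * h2_1[:, None] / m) * w2[None, :] + wu[None, :]) \
        * ((n2 * h2_2[:, None] / m) * w2[None, :] + wu[None, :])
    rows = np.arange(grid.size)
    cols = grid - 1
    s4 = np.cumsum(w4[None, :] / q2, axis=1)[rows, cols]
    se = np.cumsum(eta[None, :] * w2[None, :] / q2, axis=1)[rows, cols]
    see = np.cumsum(eta[None, :] ** 2 / q2, axis=1)[rows, cols]

    scale = m ** 2 / (float(n1) * n2)
    theo = scale / s4
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.maximum(see - se ** 2 / s4, 0.0)
        emp = np.where(grid >= 3, theo * resid / np.maximum(grid - 1, 1), 0.0)
    v = np.maximum(theo, emp)
    if not np.isfinite(v).any():
        return None, grid, v
    k_star = int(grid[int(np.nanargmin(np.where(np.isfinite(v), v, np.inf)))])
    return k_star, grid, v


def estimate_block(z1_t, z2_t, w, n1, n2, m, a_hat, var_a,
                   k_min: int = DEFAULT_K_MIN, k_max: int | None = None,
                   block: int = 0,
                   var_a_df: int | None = None) -> LocalCovarianceEstimate:
    """Full per-block estimate: adaptive K, rho_hat, variance split, p value,
    heritabilities and (when stable) the local correlation.

    ``var_a_df`` — degrees of freedom of the jackknife behind ``var_a``
    (block count minus one); when given, the p value uses a t reference
    with Welch-Satterthwaite effective df instead of the normal.
    """
    k_star, _, _ = select_k(z1_t, z2_t, w, n1, n2, m, a_hat,
                            k_min=k_min, k_max=k_max)
    if k_star is None:
        return LocalCovarianceEstimate(
            block=block, rho=np.nan, var_conditional=np.nan,
            var_intercept_prop=np.nan, var_total=np.nan, k=0, m=m,
            h2_1=np.nan, h2_2=np.nan, p_value=np.nan,
            status="not_estimable")

    h2_1_raw = local_h2_mom(z1_t, w, n1, m, k_star)
    h2_2_raw = local_h2_mom(z2_t, w, n2, m, k_star)
    q2 = compute_weights(w[:k_star], h2_1_raw, h2_2_raw, n1, n2, m)
    eta = compute_eta(z1_t[:k_star], z2_t[:k_star], w[:k_star], a_hat)
    rho = wls_rho(eta, w, q2, k_star, n1, n2, m)
    var_theo = theoretical_var(w, q2, k_star, n1, n2, m)
    if k_star >= 3:
        var_cond = empirical_var(eta, w, q2, k_star, n1, n2, m)
    else:
        var_cond = var_theo
        log.info("block %d: K=%d < 3, using theoretical variance", block, k_star)
    var_prop = intercept_var_propagation(w, q2, k_star, n1, n2, m, var_a)
    var_tot = total_var(var_cond, var_prop)

    status = "estimated"
    if var_tot > 0:
        # the test guards the residual-based variance with its analytic
        # floor at the selected rank: the rank search minimizes
        # max(theoretical, empirical), so the residual term evaluated at
        # the argmin inherits selection optimism
        p = wald_test_t(rho, max(var_cond, var_theo), var_prop, k_star,
                        var_a_df)
    else:
        p = np.nan
        status = "degenerate_variance"

    q1_t = (n1 * max(h2_1_raw, 0.0) / m) * w[:k_star] ** 2 + w[:k_star]
    q2_t = (n2 * max(h2_2_raw, 0.0) / m) * w[:k_star] ** 2 + w[:k_star]
    corr, corr_se = local_correlation(
        rho, var_tot, h2_1_raw, h2_2_raw,
        local_h2_var(w, q1_t, n1, m, k_star),
        local_h2_var(w, q2_t, n2, m, k_star))

    return LocalCovarianceEstimate(
        block=block, rho=rho, var_conditional=var_cond,
        var_intercept_prop=var_prop, var_total=var_tot, k=k_star, m=m,
        h2_1=h2_1_raw, h2_2=h2_2_raw, p_value=p, corr=corr, corr_se=corr_se,
        status=status)


# ---------------------------------------------------------------------------
# scale conversion and multiple testing


def liability_constant(params: LiabilityScaleParams) -> float:
    """Positive constant c with rho_observed = c * rho_liability."""
    phi1 = stats.norm.pdf(params.tau1)
    phi2 = stats.norm.pdf(params.tau2)
    p1, p2 = params.sample_prev1, params.sample_prev2
    k1, k2 = params.pop_prev1, params.pop_prev2
    return float(phi1 * phi2 * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
                 / (k1 * (1 - k1) * k2 * (1 - k2)))


def liability_convert(rho_obs: float, params: LiabilityScaleParams) -> float:
    """Observed-scale to liability-scale genetic covariance (sign preserved)."""
    return rho_obs / liability_constant(params)


def liability_convert_inverse(rho_liab: float,
                              params: LiabilityScaleParams) -> float:
    """Liability-scale back to observed-scale genetic covariance."""
    return rho_liab * liability_constant(params)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at FDR level q."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, float)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
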
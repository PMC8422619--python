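import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from localcov import local
from localcov.local import (LiabilityScaleParams, bh_fdr,
                            bonferroni_threshold, compute_eta,
                            compute_weights, empirical_var, estimate_block,
                            intercept_var_propagation, liability_constant,
                            liability_convert, liability_convert_inverse,
                            local_correlation, local_h2_mom, select_k,
                            theoretical_var, total_var, wald_test,
                            wald_test_t, wls_rho)


def _instance(rng, k=None):
    k = k or rng.integers(3, 12)
    w = np.sort(rng.uniform(0.1, 3.0, k))[::-1]
    eta = rng.standard_normal(k)
    q2 = rng.uniform(0.5, 2.0, k)
    n1, n2 = rng.integers(100, 1000, 2)
    m = int(rng.integers(k, 5 * k))
    return eta, w, q2, k, int(n1), int(n2), m


class TestH2MoM:
    def test_pure_null_moments_give_zero(self):
        w = np.array([3.0, 2.0, 1.0])
        z = np.sqrt(w)  # z^2 = w exactly
        assert local_h2_mom(z, w, 100, 10, 3) == pytest.approx(0.0, abs=1e-12)

    def test_plugin_identity_recovers_h2(self):
        w = np.array([4.0, 2.5, 1.5, 0.8])
        n, m, h2 = 500, 20, 0.3
        z = np.sqrt(n * h2 / m * w ** 2 + w)
        assert local_h2_mom(z, w, n, m, 4) == pytest.approx(h2, rel=1e-12)

    def test_negative_raw_value_preserved_and_zero_eigenvalue_rejected(self):
        w = np.array([2.0, 1.0])
        raw = local_h2_mom(np.zeros(2), w, 100, 10, 2)
        assert raw < 0  # raw estimate may go negative; clipping is downstream
        with pytest.raises(ValueError, match="eigenvalue"):
            local_h2_mom(np.ones(3), np.array([1.0, 0.0, 0.0]), 100, 10, 2)


class TestWeightsAndEta:
    def test_null_heritability_limit(self):
        w = np.array([2.0, 0.5])
        np.testing.assert_allclose(compute_weights(w, 0, 0, 10, 10, 5), w ** 2)

    def test_direct_substitution(self):
        # w = 1, h2 = 0.5 m / n on both traits: q^2 = ((0.5+1)*1)^2
        q2 = compute_weights(np.array([1.0]), 0.05, 0.05, 100, 100, 10)
        np.testing.assert_allclose(q2, [2.25])

    def test_monotone_in_heritability(self, rng):
        w = rng.uniform(0.2, 3, 6)
        lo = compute_weights(w, 0.1, 0.2, 300, 400, 50)
        hi = compute_weights(w, 0.2, 0.2, 300, 400, 50)
        assert (hi > lo).all()

    def test_eta_forms(self):
        w = np.array([2.0, 1.0])
        z1 = np.array([1.0, 3.0])
        z2 = np.array([2.0, -1.0])
        np.testing.assert_allclose(compute_eta(z1, z2, w, 0.0), z1 * z2)
        np.testing.assert_allclose(compute_eta(np.zeros(2), z2, w, 0.5),
                                   -0.5 * w)


class TestWLSAndVariances:
    def test_hand_example(self):
        # w=(2,1), q2=(1,1), eta=(4,1): slope 17/17=1, rho = m/sqrt(n1 n2) * 1
        rho = wls_rho(np.array([4.0, 1.0]), np.array([2.0, 1.0]),
                      np.array([1.0, 1.0]), 2, 1, 1, 2)
        assert rho == pytest.approx(2.0)

    def test_matches_bruteforce_linear_model_oracles(self):
        """wls_rho / Eq.5 / Eq.6 / Eq.7 against dense WLS algebra."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            eta, w, q2, k, n1, n2, m = _instance(rng)
            X = (w ** 2)[:, None]
            W = np.diag(1.0 / q2)
            xtwx = (X.T @ W @ X).item()
            beta = (X.T @ W @ eta).item() / xtwx
            scale = m / np.sqrt(n1 * n2)
            assert wls_rho(eta, w, q2, k, n1, n2, m) == \
                pytest.approx(scale * beta, rel=1e-10)
            assert theoretical_var(w, q2, k, n1, n2, m) == \
                pytest.approx(scale ** 2 / xtwx, rel=1e-10)
            resid = eta - X[:, 0] * beta
            sigma2 = (resid @ W @ resid).item() / (k - 1)
            assert empirical_var(eta, w, q2, k, n1, n2, m) == \
                pytest.approx(scale ** 2 * sigma2 / xtwx, rel=1e-10, abs=1e-12)
            # rho_hat is linear in a_hat: exact derivative by differencing
            var_a = float(rng.uniform(0.1, 2.0))
            r_plus = wls_rho(compute_eta(np.zeros(k), np.zeros(k), w, -1.0),
                             w, q2, k, n1, n2, m)
            assert intercept_var_propagation(w, q2, k, n1, n2, m, var_a) == \
                pytest.approx(r_plus ** 2 * var_a, rel=1e-10)

    def test_perfect_fit_has_zero_empirical_variance(self):
        w = np.array([2.0, 1.0, 0.5])
        eta = 3.0 * w ** 2
        assert empirical_var(eta, w, np.ones(3), 3, 10, 10, 5) == 0.0

    def test_theoretical_var_scaling_and_monotonicity(self, rng):
        eta, w, q2, k, n1, n2, m = _instance(rng, k=8)
        v = theoretical_var(w, q2, k, n1, n2, m)
        assert theoretical_var(w, q2, k, n1, n2, 2 * m) == \
            pytest.approx(4 * v, rel=1e-12)
        seq = [theoretical_var(w, q2, kk, n1, n2, m) for kk in range(2, k + 1)]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_identity_ld_reduces_intercept_propagation(self):
        # w = 1 everywhere: (sum w^3/q^2 / sum w^4/q^2)^2 = 1
        k, n1, n2, m, var_a = 6, 50, 80, 30, 0.7
        q2 = np.full(k, 1.3)
        v = intercept_var_propagation(np.ones(k), q2, k, n1, n2, m, var_a)
        assert v == pytest.approx(m ** 2 / (n1 * n2) * var_a, rel=1e-12)
        assert intercept_var_propagation(np.ones(k), q2, k, n1, n2, m, 0) == 0

    def test_total_var_is_the_sum(self):
        assert total_var(0.1, 0.05) == pytest.approx(0.15)
        assert total_var(0.3, 0.0) == 0.3


class TestAdaptiveK:
    def test_respects_rank_cap_and_lower_bound(self, rng):
        m = 40
        w = np.sort(rng.uniform(0.5, 3, m))[::-1]
        z1, z2 = rng.standard_normal((2, m))
        k, grid, v = select_k(z1, z2, w, 200, 200, m, 0.0, k_min=10, k_max=25)
        assert 10 <= k <= 25
        assert grid[0] == 10 and grid[-1] == 25

    def test_tiny_block_uses_all_components(self, rng):
        m = 6
        w = np.sort(rng.uniform(0.5, 2, m))[::-1]
        z1, z2 = rng.standard_normal((2, m))
        k, grid, _ = select_k(z1, z2, w, 100, 100, m, 0.0, k_min=10)
        assert k == m and list(grid) == [m]

    def test_argmin_is_smallest_on_ties(self, rng):
        # identical information in every component makes v(K) extremely
        # flat; re-running must be deterministic and pick the first argmin
        m = 30
        w = np.sort(rng.uniform(0.5, 3, m))[::-1]
        z1, z2 = rng.standard_normal((2, m))
        k1, _, v = select_k(z1, z2, w, 100, 100, m, 0.0)
        grid = np.arange(10, m + 1)
        assert k1 == grid[int(np.argmin(np.where(np.isfinite(v), v, np.inf)))]


class TestTests:
    def test_wald_examples(self):
        assert wald_test(0.0, 1.0) == pytest.approx(1.0)
        assert wald_test(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)
        assert wald_test(-0.3, 0.04) == pytest.approx(wald_test(0.3, 0.04))
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    def test_t_reference_reduces_to_normal_at_large_df(self):
        p_t = wald_test_t(2.0, 1.0, 1.0, 100000, 100000)
        p_n = wald_test(2.0, 2.0)
        assert p_t == pytest.approx(p_n, rel=1e-3)
        # small jackknife df gives a heavier tail, hence larger p
        assert wald_test_t(2.0, 0.1, 1.9, 50, 5) > p_n

    def test_bonferroni_reported_thresholds(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert f"{bonferroni_threshold(0.05, 435):.1e}" == "1.1e-04"
        assert f"{bonferroni_threshold(0.05, 1_006_072):.1e}" == "5.0e-08"

    def test_bh_fdr_step_up(self):
        assert not bh_fdr(np.ones(5), 0.1).any()
        flags = bh_fdr([0.01, 0.02, 0.9], 0.1)
        assert list(flags) == [True, True, False]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20),
           st.floats(0.01, 0.2), st.floats(0.01, 0.2))
    def test_bh_monotone_in_q(self, ps, q_lo, q_extra):
        lo, hi = sorted([q_lo, q_lo + q_extra])
        assert bh_fdr(ps, lo).sum() <= bh_fdr(ps, hi).sum()


class TestCorrelation:
    def test_arithmetic_and_guards(self):
        corr, se = local_correlation(0.5, 0.01, 1.0, 0.25, 0.01, 0.01)
        assert corr == pytest.approx(1.0)
        assert local_correlation(0.1, 0.01, -0.2, 0.5, 0.01, 0.01) == (None, None)
        corr0, se0 = local_correlation(0.0, 0.01, 0.5, 0.5, 0.01, 0.01)
        assert corr0 == 0.0 and se0 > 0


class TestLiability:
    def test_half_prevalence_constant(self):
        params = LiabilityScaleParams(0.5, 0.5, 0.5, 0.5)
        expected = stats.norm.pdf(0) ** 2 * 0.25 / 0.0625
        assert liability_constant(params) == pytest.approx(expected, rel=1e-12)
        assert liability_convert(1.0, params) == pytest.approx(1 / expected)
        assert liability_convert(0.0, params) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(*(st.floats(0.01, 0.99),) * 4,
           st.floats(-0.5, 0.5))
    def test_round_trip_and_sign_preservation(self, p1, k1, p2, k2, rho):
        params = LiabilityScaleParams(p1, k1, p2, k2)
        back = liability_convert_inverse(liability_convert(rho, params), params)
        assert back == pytest.approx(rho, abs=1e-12)
        assert np.sign(liability_convert(rho, params)) == np.sign(rho)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            LiabilityScaleParams(0.5, 1.5, 0.5, 0.5)


class TestEstimateBlock:
    def test_full_block_pipeline_sane(self, rng):
        m = 60
        w = np.sort(rng.uniform(0.3, 4, m))[::-1]
        h2 = 0.02
        n = 2000
        z1 = rng.standard_normal(m) * np.sqrt(n * h2 / m * w ** 2 + w)
        z2 = rng.standard_normal(m) * np.sqrt(n * h2 / m * w ** 2 + w)
        est = estimate_block(z1, z2, w, n, n, m, 0.0, 0.01, var_a_df=11)
        assert est.status == "estimated"
        assert 10 <= est.k <= m
        assert est.var_total == pytest.approx(
            est.var_conditional + est.var_intercept_prop)
        assert 0 < est.p_value <= 1
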
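import numpy as np
import pytest
from scipy import stats

from sparseassoc.firth import fit_mle
from sparseassoc.score import (
    adjusted_score_test,
    excess_kurtosis,
    kurtosis_df,
    quadform_kurtosis,
    quadform_variance_correction,
    saddlepoint_pvalue,
    saddlepoint_pvalues,
    score_components,
    standard_score_test,
)
from conftest import make_toy_cohort


def _full_loglik(beta, y, Xfull):
    eta = Xfull @ beta
    return np.sum(y * eta - np.logaddexp(0.0, eta))


class TestScoreComponentsAgainstNumericDerivatives:
    """Oracle: finite differences of the full-model log-likelihood at the
    null fit (genotype coefficient fixed at zero)."""

    def setup_method(self):
        self.y, self.X, G = make_toy_cohort(n=250, m=3, seed=31)
        self.g = G[:, 0]
        self.Xfull = np.column_stack([self.X, self.g])
        null = fit_mle(self.y, self.X)
        self.beta0 = np.append(null.coefficients, 0.0)
        self.sc = score_components(self.y, self.X, self.g, null_fit=null)

    def test_score_is_gradient_component(self):
        h = 1e-6
        e = np.zeros(4)
        e[3] = h
        num_U = (
            _full_loglik(self.beta0 + e, self.y, self.Xfull)
            - _full_loglik(self.beta0 - e, self.y, self.Xfull)
        ) / (2 * h)
        assert self.sc.U == pytest.approx(num_U, abs=1e-4 * max(1.0, abs(num_U)))

    def test_variance_is_efficient_information(self):
        # numeric Hessian of -loglik, then the Schur complement for the
        # genotype coordinate
        h = 1e-5
        p = 4
        H = np.zeros((p, p))
        for a in range(p):
            for b in range(p):
                ea, eb = np.zeros(p), np.zeros(p)
                ea[a], eb[b] = h, h
                H[a, b] = (
                    _full_loglik(self.beta0 + ea + eb, self.y, self.Xfull)
                    - _full_loglik(self.beta0 + ea - eb, self.y, self.Xfull)
                    - _full_loglik(self.beta0 - ea + eb, self.y, self.Xfull)
                    + _full_loglik(self.beta0 - ea - eb, self.y, self.Xfull)
                ) / (4 * h * h)
        info = -H
        V_num = info[3, 3] - info[3, :3] @ np.linalg.solve(info[:3, :3], info[:3, 3])
        assert self.sc.V == pytest.approx(V_num, rel=1e-4)

    def test_residualized_genotype_orthogonal_to_design(self):
        s = self.sc.null_probs * (1 - self.sc.null_probs)
        np.testing.assert_allclose(self.X.T @ (s * self.sc.g_adj), 0.0, atol=1e-8)


class TestStandardScoreTest:
    def test_p_from_chi2_reference(self):
        y, X, G = make_toy_cohort(n=300, m=2, seed=5)
        sc = score_components(y, X, G[:, 1])
        res = standard_score_test(sc)
        assert res.statistic == pytest.approx(sc.U**2 / sc.V)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_degenerate_variance_falls_back(self):
        y, X, _ = make_toy_cohort(n=100, m=1, seed=9)
        sc = score_components(y, X, np.zeros(100))
        res = standard_score_test(sc)
        assert res.p_value == 1.0 and res.status.value == "fallback"


class TestVarianceCorrection:
    def test_matches_monte_carlo_variance_of_quadratic_form(self):
        rng = np.random.default_rng(77)
        n = 30
        pi = rng.uniform(0.05, 0.6, n)
        g = rng.binomial(2, 0.15, n).astype(float)
        s = pi * (1 - pi)
        V = float(g @ (s * g))
        analytic = 2.0 * V**2 + quadform_variance_correction(g**2, s)
        draws = (rng.random((400_000, n)) < pi) - pi
        Q = (draws @ g) ** 2
        mc_var = float(np.var(Q))
        # MC SE of a variance estimate via the fourth moment
        se = np.sqrt(np.var((Q - Q.mean()) ** 2) / Q.size)
        assert abs(analytic - mc_var) < 4 * se

    def test_zero_for_gaussian_limit(self):
        # the correction vanishes when s = 1/6 exactly: s - 6 s^2 = 0
        s = np.full(5, 1.0 / 6.0)
        assert quadform_variance_correction(np.ones(5), s) == pytest.approx(0.0)


class TestKurtosisHelpers:
    def test_excess_kurtosis_matches_scipy_bias_corrected(self):
        rng = np.random.default_rng(4)
        x = rng.chisquare(3.0, 500)
        assert excess_kurtosis(x) == pytest.approx(
            stats.kurtosis(x, fisher=True, bias=False), rel=1e-10
        )

    def test_df_mapping_floor_and_cap(self):
        assert kurtosis_df(12.0) == pytest.approx(1.0)
        assert kurtosis_df(1e9) == 0.5
        assert kurtosis_df(-1.0) == 1e5
        assert kurtosis_df(12.0 / 7.5) == pytest.approx(7.5)


class TestAdjustedScoreTest:
    def test_variance_mode_formula(self):
        y, X, G = make_toy_cohort(n=300, m=2, seed=15)
        sc = score_components(y, X, G[:, 0])
        res = adjusted_score_test(sc, "variance")
        s = sc.null_probs * (1 - sc.null_probs)
        sigma = np.sqrt(2 * sc.V**2 + quadform_variance_correction(sc.g_adj**2, s))
        t = (sc.U**2 - sc.V) / sigma * np.sqrt(2.0) + 1.0
        assert res.p_value == pytest.approx(stats.chi2.sf(max(t, 0.0), 1))

    def test_kurtosis_mode_deterministic_given_seed(self):
        y, X, G = make_toy_cohort(n=300, m=2, seed=15)
        sc = score_components(y, X, G[:, 0])
        r1 = adjusted_score_test(sc, "variance+kurtosis", B=2000, seed=42)
        r2 = adjusted_score_test(sc, "variance+kurtosis", B=2000, seed=42)
        assert r1.p_value == r2.p_value

    def test_kurtosis_mode_requires_enough_bootstrap(self):
        y, X, G = make_toy_cohort(n=200, m=1, seed=2)
        sc = score_components(y, X, G[:, 0])
        with pytest.raises(ValueError, match="B >= 1000"):
            adjusted_score_test(sc, "variance+kurtosis", B=100)

    def test_adjustments_converge_to_standard_for_common_variant(self):
        # dense genotype, moderate n: all three tests should nearly agree
        rng = np.random.default_rng(123)
        n = 4000
        g = rng.binomial(2, 0.3, n).astype(float)
        X = np.ones((n, 1))
        y = (rng.random(n) < 0.4).astype(float)
        sc = score_components(y, X, g)
        p_std = standard_score_test(sc).p_value
        p_var = adjusted_score_test(sc, "variance").p_value
        p_kurt = adjusted_score_test(sc, "variance+kurtosis", B=20_000, seed=1).p_value
        assert p_var == pytest.approx(p_std, abs=0.01)
        assert p_kurt == pytest.approx(p_std, abs=0.02)


class TestAnalyticKurtosis:
    def test_matches_large_bootstrap_estimate(self):
        y, X, G = make_toy_cohort(n=350, m=3, seed=55)
        sc = score_components(y, X, G[:, 0])
        gamma = quadform_kurtosis(sc.g_adj, sc.null_probs)
        rng = np.random.default_rng(0)
        boot = []
        for _ in range(20):
            Ustar = ((rng.random((50_000, len(y))) < sc.null_probs) - sc.null_probs) @ sc.g_adj
            boot.append(excess_kurtosis(Ustar**2))
        est = float(np.mean(boot))
        se = float(np.std(boot) / np.sqrt(len(boot)))
        assert abs(gamma - est) <= 4 * se

    def test_normal_limit_is_chi_square_kurtosis(self):
        rng = np.random.default_rng(1)
        n = 50_000
        a = rng.normal(0.0, 1.0, n)
        pi0 = rng.uniform(0.1, 0.4, n)
        assert quadform_kurtosis(a, pi0) == pytest.approx(12.0, abs=0.05)

    def test_vectorized_matches_per_column(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0.0, 1.0, (80, 3)) * (rng.random((80, 3)) < 0.2)
        pi0 = rng.uniform(0.05, 0.5, 80)
        per_col = [quadform_kurtosis(A[:, j], pi0) for j in range(3)]
        np.testing.assert_allclose(quadform_kurtosis(A, pi0), per_col, rtol=1e-12)

    def test_analytic_mode_needs_no_bootstrap(self):
        y, X, G = make_toy_cohort(n=300, m=2, seed=8)
        sc = score_components(y, X, G[:, 0])
        res = adjusted_score_test(sc, "variance+kurtosis", moments="analytic")
        assert 0.0 <= res.p_value <= 1.0
        assert res.df_or_params["B"] == 0
        # deterministic without a seed
        res2 = adjusted_score_test(sc, "variance+kurtosis", moments="analytic")
        assert res.p_value == res2.p_value

class TestSaddlepoint:
    """Oracle: Monte-Carlo tail probabilities of U = a'(y - pi0)."""

    def test_matches_monte_carlo_tails(self):
        rng = np.random.default_rng(6)
        n = 400
        a = rng.normal(0.0, 1.0, n) * (rng.random(n) < 0.25)
        pi0 = rng.uniform(0.1, 0.5, n)
        V = float(a @ (pi0 * (1.0 - pi0) * a))
        us = np.array([0.5, 1.5, 2.5]) * np.sqrt(V)
        counts = np.zeros(us.size)
        N = 0
        for _ in range(4):
            draws = ((rng.random((250_000, n)) < pi0) - pi0) @ a
            counts += (np.abs(draws)[:, None] >= us[None, :]).sum(axis=0)
            N += draws.shape[0]
        for k, u in enumerate(us):
            p_mc = counts[k] / N
            se = np.sqrt(p_mc * (1.0 - p_mc) / N)
            assert abs(saddlepoint_pvalue(u, a, pi0) - p_mc) < 4 * se

    def test_dense_limit_matches_chi_square(self):
        rng = np.random.default_rng(7)
        n = 5000
        a = rng.normal(0.0, 1.0, n)
        pi0 = rng.uniform(0.2, 0.6, n)
        V = float(a @ (pi0 * (1.0 - pi0) * a))
        for z in (0.3, 1.0, 2.0, 3.0):
            p = saddlepoint_pvalue(z * np.sqrt(V), a, pi0)
            assert p == pytest.approx(stats.chi2.sf(z**2, 1), rel=0.01)

    def test_monotone_in_statistic(self):
        rng = np.random.default_rng(8)
        n = 150
        a = rng.normal(0.0, 1.0, n) * (rng.random(n) < 0.1)
        pi0 = rng.uniform(0.1, 0.4, n)
        V = float(a @ (pi0 * (1.0 - pi0) * a))
        us = np.linspace(0.0, 4.0, 25) * np.sqrt(V)
        ps = [saddlepoint_pvalue(u, a, pi0) for u in us]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert all(p2 <= p1 + 1e-9 for p1, p2 in zip(ps, ps[1:]))
        assert ps[0] == 1.0

    def test_degenerate_and_vectorized(self):
        pi0 = np.full(60, 0.3)
        assert saddlepoint_pvalues(np.array([0.5]), np.zeros((60, 1)), pi0)[0] == 1.0
        rng = np.random.default_rng(9)
        A = rng.normal(0.0, 1.0, (60, 3)) * (rng.random((60, 3)) < 0.3)
        u = np.array([0.4, -1.1, 2.0])
        batch = saddlepoint_pvalues(u, A, pi0)
        single = [saddlepoint_pvalue(u[j], A[:, j], pi0) for j in range(3)]
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_sign_symmetric(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1.0, 80) * (rng.random(80) < 0.2)
        pi0 = rng.uniform(0.2, 0.5, 80)
        assert saddlepoint_pvalue(1.3, a, pi0) == pytest.approx(
            saddlepoint_pvalue(-1.3, -a, pi0), rel=1e-12
        )
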
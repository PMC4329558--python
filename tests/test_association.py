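import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from pathartp.association import (
    CovariateDesign,
    GenotypePCA,
    build_design,
    compute_pcs,
    fit_null_logistic,
    fit_snp_logistic,
    score_test_pvalues,
)


def _two_by_two_dataset():
    # binary dosage: cases 30 exposed / 70 not, controls 10 / 90
    g = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 10 + [0.0] * 90)
    y = np.array([1] * 100 + [0] * 100)
    return g, y


class TestWaldFit:
    def test_two_by_two_closed_form(self):
        g, y = _two_by_two_dataset()
        res = fit_snp_logistic(g, y)
        want_or = (30 * 90) / (70 * 10)
        assert res.or_ == pytest.approx(want_or, rel=1e-8)
        assert res.beta == pytest.approx(np.log(want_or), abs=1e-8)
        assert res.ci_low < res.or_ < res.ci_high
        assert res.or_ == pytest.approx(np.exp(res.beta))

    def test_null_fixture_or_near_one(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 2000).astype(float)
        y = np.array([1, 0] * 1000)
        res = fit_snp_logistic(g, y)
        assert res.or_ == pytest.approx(1.0, abs=0.15)
        assert res.p > 0.01

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_reference_glm(self, seed):
        """Newton ML fit agrees with an independently fitted unpenalized
        logistic regression to |d beta| < 1e-6."""
        rng = np.random.default_rng(1000 + seed)
        n = 120
        g = rng.binomial(2, rng.uniform(0.15, 0.45), n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        age = rng.normal(size=n)
        eta = -0.3 + 0.4 * g + 0.3 * sex - 0.2 * age
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        if np.ptp(g) == 0 or len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        design = CovariateDesign(
            np.column_stack([np.ones(n), sex, age]), ["intercept", "sex", "age"]
        )
        res = fit_snp_logistic(g, y, design)
        if not res.ok:
            pytest.skip("flagged fit (separation) — covered elsewhere")
        ref = LogisticRegression(C=np.inf, solver="newton-cholesky",
                                 tol=1e-12, max_iter=500)
        ref.fit(np.column_stack([sex, age, g]), y)
        assert res.beta == pytest.approx(ref.coef_[0][-1], abs=1e-6)

    def test_label_swap_flips_beta(self):
        g, y = _two_by_two_dataset()
        a = fit_snp_logistic(g, y)
        b = fit_snp_logistic(g, 1 - y)
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)
        assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_monomorphic_flagged(self):
        res = fit_snp_logistic(np.zeros(10), np.array([1] * 5 + [0] * 5))
        assert res.status == "monomorphic" and np.isnan(res.beta)

    def test_single_class_flagged(self):
        res = fit_snp_logistic(np.array([0.0, 1, 2, 1]), np.ones(4, dtype=int))
        assert res.status == "one_class"

    def test_separation_flagged_not_crash(self):
        g = np.array([2.0] * 10 + [0.0] * 10)
        y = np.array([1] * 10 + [0] * 10)
        res = fit_snp_logistic(g, y)
        assert res.status in ("ok", "not_converged")
        if res.status == "ok":
            assert res.se < 1e3  # sanity: never report a degenerate Wald row

    def test_complete_case_count(self):
        g = np.array([0.0, 1, np.nan, 2, 1, np.nan, 0, 1])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = fit_snp_logistic(g, y)
        assert res.n_used == 6

    def test_wald_p_uniform_under_null(self):
        """Global null: n=1000, 500 SNPs -> KS distance below 0.05."""
        rng = np.random.default_rng(77)
        n, m = 1000, 500
        y = np.array([1] * 500 + [0] * 500)
        mafs = rng.uniform(0.1, 0.5, m)
        G = rng.binomial(2, mafs, (n, m)).astype(float)
        ps = [fit_snp_logistic(G[:, j], y).p for j in range(m)]
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.05


class TestDesign:
    def test_categorical_encoding(self):
        frame = pd.DataFrame({"study": ["a", "b", "c", "a"],
                              "sex": ["m", "f", "m", "f"]})
        d = build_design(frame, categorical=["study", "sex"])
        assert d.columns[0] == "intercept"
        assert d.matrix.shape == (4, 4)  # intercept + 2 study + 1 sex

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            CovariateDesign(np.ones((5, 2)), ["intercept", "dup"])


class TestScoreTest:
    def test_orthogonal_dosage_gives_p_one(self):
        y = np.array([1.0, 0, 1, 0])
        g = np.array([[1.0], [1], [1], [1]]) * 2  # constant -> V = 0
        p = score_test_pvalues(g, y)
        assert p[0] == 1.0

    def test_equals_trend_statistic_without_covariates(self):
        """Intercept-only score statistic equals the 2x3-table trend
        statistic computed directly from the table margins."""
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, 300).astype(float)
        y = (rng.random(300) < 0.4).astype(float)
        p = score_test_pvalues(g[:, None], y)
        # direct 2x3 table arithmetic
        N, R = len(y), y.sum()
        n_g = np.array([(g == k).sum() for k in (0, 1, 2)])
        r_g = np.array([y[g == k].sum() for k in (0, 1, 2)])
        t = np.array([0.0, 1, 2])
        U = np.sum(t * r_g) - (R / N) * np.sum(t * n_g)
        V = (R / N) * (1 - R / N) * (np.sum(t**2 * n_g) - np.sum(t * n_g) ** 2 / N)
        want = stats.chi2.sf(U**2 / V, 1)
        assert p[0] == pytest.approx(want, rel=1e-10)

    def test_rank_agreement_with_wald(self):
        rng = np.random.default_rng(8)
        n, m = 500, 200
        mafs = rng.uniform(0.1, 0.5, m)
        G = rng.binomial(2, mafs, (n, m)).astype(float)
        beta = np.where(rng.random(m) < 0.2, 0.4, 0.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-(G - 2 * mafs) @ beta))).astype(int)
        cov = rng.normal(size=n)
        design = CovariateDesign(np.column_stack([np.ones(n), cov]),
                                 ["intercept", "z"])
        p_score = score_test_pvalues(G, y, design)
        p_wald = np.array(
            [fit_snp_logistic(G[:, j], y, design).p for j in range(m)]
        )
        rho = stats.spearmanr(p_score, p_wald).statistic
        assert rho > 0.99

    def test_null_irls_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.integers(0, 2, n)])
        y = (rng.random(n) < 0.35).astype(float)
        mu = fit_null_logistic(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(mu, ref.fittedvalues, atol=1e-8)


class TestGenotypePCA:
    def _two_pops(self, n=200, m=150, delta=0.3, seed=0):
        rng = np.random.default_rng(seed)
        pop = np.array([0] * (n // 2) + [1] * (n // 2))
        f0 = rng.uniform(0.15, 0.35, m)
        sign = np.where(rng.random(m) < 0.5, 1, -1)
        f1 = np.clip(f0 + sign * delta, 0.02, 0.98)
        F = np.where(pop[:, None] == 1, f1, f0)
        return rng.binomial(2, F).astype(float), pop

    def test_pc1_separates_subpopulations(self):
        G, pop = self._two_pops()
        pcs = compute_pcs(G, 2)
        r = abs(stats.pointbiserialr(pop, pcs[:, 0]).statistic)
        assert r > 0.9

    def test_duplicated_samples_identical_coordinates(self):
        G, _ = self._two_pops(n=60, m=40)
        G2 = np.vstack([G, G[:5]])
        pcs = compute_pcs(G2, 2)
        assert np.allclose(pcs[:5], pcs[60:], atol=1e-9)

    def test_k_zero_empty(self):
        G, _ = self._two_pops(n=30, m=10)
        assert compute_pcs(G, 0).shape == (30, 0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            compute_pcs(np.zeros((5, 3)), 5)

    def test_snp_order_invariance_up_to_sign(self):
        G, _ = self._two_pops(n=80, m=60, seed=3)
        rng = np.random.default_rng(9)
        perm = rng.permutation(G.shape[1])
        a = compute_pcs(G, 3)
        b = compute_pcs(G[:, perm], 3)
        for k in range(3):
            assert min(
                np.abs(a[:, k] - b[:, k]).max(),
                np.abs(a[:, k] + b[:, k]).max(),
            ) < 1e-8

    def test_missing_values_mean_imputed(self):
        G, _ = self._two_pops(n=50, m=30)
        G[0, 0] = np.nan
        pcs = compute_pcs(G, 2)
        assert np.isfinite(pcs).all()

    def test_transform_matches_fit_transform(self):
        G, _ = self._two_pops(n=50, m=30, seed=5)
        pca = GenotypePCA(2)
        u = pca.fit_transform(G)
        assert np.allclose(pca.transform(G), u, atol=1e-8)
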
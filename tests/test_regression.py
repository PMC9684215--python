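import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma

from episubnet.diffnet import InteractionNetwork
from episubnet.regression import (
    GPriorSpec,
    best_subset,
    biological_relatedness,
    coefficient_significance,
    confidence_score,
    expected_bic,
    no_prior_baseline,
    posterior_beta,
    posterior_sigma2,
    relatedness_matrix,
    subnetwork_correlation_test,
    tune_mu,
)
from oracle_utils import nig_posterior_oracle


def toy_problem(seed, n=20, k=2, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    beta = rng.standard_normal(k) if beta is None else np.asarray(beta, float)
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestBiologicalRelatedness:
    def test_no_cross_edges(self):
        ppi = InteractionNetwork([("p1", "p2")])
        assert biological_relatedness({"p1", "p2"}, {"r1"}, ppi) == 0.0

    def test_complete_bipartite(self):
        preds = [f"p{i}" for i in range(5)]
        resps = [f"r{i}" for i in range(5)]
        ppi = InteractionNetwork([(p, r) for p in preds for r in resps])
        assert biological_relatedness(preds, resps, ppi) == pytest.approx(5.0)

    def test_adding_edge_never_decreases(self):
        edges = [("p0", "r0")]
        r0 = biological_relatedness(["p0", "p1"], ["r0"], InteractionNetwork(edges))
        r1 = biological_relatedness(
            ["p0", "p1"], ["r0"], InteractionNetwork(edges + [("p1", "r0")])
        )
        assert r1 >= r0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            biological_relatedness(set(), {"r"}, InteractionNetwork([("a", "b")]))


class TestPosteriorBeta:
    def test_zero_g_returns_prior_mean(self):
        X, y = toy_problem(0)
        beta, _ = posterior_beta(X, y, 0.0)
        assert np.allclose(beta, 0.0)

    def test_unit_g_halves_ols(self):
        X, y = toy_problem(1, k=1)
        ols = float(np.linalg.lstsq(X, y, rcond=None)[0][0])
        beta, _ = posterior_beta(X, y, 1.0)
        assert beta[0] == pytest.approx(0.5 * ols, abs=1e-12)

    def test_large_g_approaches_ols(self):
        X, y = toy_problem(2)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta, _ = posterior_beta(X, y, 1e9)
        assert np.allclose(beta, ols, atol=1e-6)

    def test_shrinkage_monotone_in_g(self):
        X, y = toy_problem(3, k=1)
        gs = [0.0, 0.5, 1.0, 5.0, 100.0]
        mags = [abs(posterior_beta(X, y, g)[0][0]) for g in gs]
        assert (np.diff(mags) >= -1e-12).all()

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            posterior_beta(X, x, 1.0)


class TestPosteriorSigma2:
    def test_perfect_fit_leaves_only_shrinkage_term(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 2))
        beta = np.array([0.8, -0.4])
        y = X @ beta  # exactly in the span
        g = 2.0
        a, b = posterior_sigma2(X, y, g)
        expected = beta @ X.T @ X @ beta / (2 * (1 + g))
        assert a == pytest.approx(7.5)
        assert b == pytest.approx(expected, rel=1e-10)

    def test_large_g_leaves_half_ssr(self):
        X, y = toy_problem(6)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        ssr = float(np.sum((y - X @ ols) ** 2))
        _, b = posterior_sigma2(X, y, 1e12)
        assert b == pytest.approx(ssr / 2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_conjugate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 20, int(rng.integers(1, 4))
        X = rng.standard_normal((n, k))
        y = rng.standard_normal(n)
        g = float(rng.uniform(0.2, 8))
        beta0 = rng.standard_normal(k)
        mean, cov, shape, scale = nig_posterior_oracle(X, y, g, beta0)
        bt, cs = posterior_beta(X, y, g, beta0)
        a, b = posterior_sigma2(X, y, g, beta0)
        assert np.allclose(bt, mean, atol=1e-10)
        assert np.allclose(cs, cov, atol=1e-10)
        assert a == pytest.approx(shape, abs=1e-12)
        assert b == pytest.approx(scale, abs=1e-10)


class TestExpectedBic:
    def test_digamma_identity(self):
        # E[ln sigma^2] for IG(5, 10) = ln(10) - psi(5) = 2.302585 - 1.506118
        assert np.log(10) - digamma(5) == pytest.approx(0.79647, abs=1e-5)

    def test_penalty_difference_for_equal_fits(self):
        # subsets with identical (a, b) differ in E[BIC] by dk * ln(n) exactly
        rng = np.random.default_rng(7)
        n = 50
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        e1 = expected_bic(x[:, None], y, 1e15)
        a1, b1 = posterior_sigma2(x[:, None], y, 1e15)
        e2_same_fit = n * (np.log(b1) - digamma(a1)) + 2 * np.log(n)
        assert e2_same_fit - e1 == pytest.approx(np.log(n), rel=1e-12)

    def test_noise_predictor_usually_increases_ebic(self):
        wins = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 200
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            noise = rng.standard_normal(n)
            e_true = expected_bic(x[:, None], y, 3.0)
            e_plus = expected_bic(np.column_stack([x, noise]), y, np.array([3.0, 3.0]))
            wins += e_plus > e_true
        assert wins >= 0.9 * trials


class TestBestSubset:
    @staticmethod
    def _gspec(predictors, responses, mu=1.0, value=2.0):
        r = pd.DataFrame(value, index=predictors, columns=responses)
        return GPriorSpec(r=r, mu=mu)

    def test_single_predictor_selected(self):
        X, y = toy_problem(8, k=1)
        X_all = pd.DataFrame(X, columns=["x1"])
        fit = best_subset(X_all, y, self._gspec(["x1"], ["y1"]), response="y1")
        assert fit.predictors == ("x1",)

    def test_planted_single_signal_among_noise(self):
        rng = np.random.default_rng(9)
        n = 200
        X = rng.standard_normal((n, 4))
        y = 0.3 * X[:, 0] + rng.standard_normal(n) * 0.5
        X_all = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
        fit = best_subset(X_all, y, self._gspec(X_all.columns, ["y1"]), response="y1")
        assert fit.predictors == ("x1",)

    def test_independent_response_selects_size_one(self):
        rng = np.random.default_rng(10)
        X_all = pd.DataFrame(rng.standard_normal((100, 3)), columns=["x1", "x2", "x3"])
        y = rng.standard_normal(100)
        fit = best_subset(X_all, y, self._gspec(X_all.columns, ["y1"]), response="y1")
        assert len(fit.predictors) == 1


class TestCoefficientSignificance:
    def test_fully_shrunk_coefficient_p_one(self):
        X, y = toy_problem(11, k=1)
        X_all = pd.DataFrame(X, columns=["x1"])
        gspec = GPriorSpec(r=pd.DataFrame(0.0, index=["x1"], columns=["y1"]), mu=1.0)
        fit = best_subset(X_all, y, gspec, response="y1")
        assert fit.fit.coef_p[0] == pytest.approx(1.0)

    def test_strong_association_tiny_p(self):
        rng = np.random.default_rng(12)
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.3 * rng.standard_normal(n)
        X_all = pd.DataFrame({"x1": x})
        gspec = GPriorSpec(r=pd.DataFrame(2.0, index=["x1"], columns=["y1"]), mu=1.0)
        fit = best_subset(X_all, y, gspec, response="y1")
        assert fit.fit.coef_p[0] < 1e-6

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 1))
            y = rng.standard_normal(60)
            X_all = pd.DataFrame(X, columns=["x1"])
            gspec = GPriorSpec(r=pd.DataFrame(5.0, index=["x1"], columns=["y1"]), mu=1.0)
            fit = best_subset(X_all, y, gspec, response="y1")
            pvals.append(fit.fit.coef_p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCorrelationPermutationTest:
    def test_exact_linear_combination_saturates(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((50, 2))
        y = X @ np.array([1.0, -0.5])
        B = 99
        assert subnetwork_correlation_test(X, y, B=B, seed=0) == pytest.approx(1 / (B + 1))

    def test_independent_response_not_significant(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((100, 2))
        y = rng.standard_normal(100)
        p = subnetwork_correlation_test(X, y, B=200, seed=1)
        assert p > 0.05

    def test_zero_permutations_raise(self):
        with pytest.raises(ValueError):
            subnetwork_correlation_test(np.ones((10, 1)), np.ones(10), B=0)


class TestNoPriorBaseline:
    def test_recovers_strong_signal(self):
        rng = np.random.default_rng(15)
        n = 200
        X = rng.standard_normal((n, 4))
        y = 0.6 * X[:, 1] + rng.standard_normal(n)
        X_all = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
        fit = no_prior_baseline(X_all, y)
        assert fit.predictors == ("x2",)
        assert fit.fit.coef_p[0] < 1e-6

    def test_single_predictor(self):
        X, y = toy_problem(16, k=1)
        fit = no_prior_baseline(pd.DataFrame(X, columns=["x1"]), y)
        assert fit.predictors == ("x1",)

    def test_matches_gprior_in_large_g_limit(self):
        rng = np.random.default_rng(17)
        n = 100
        X = rng.standard_normal((n, 2))
        y = X @ np.array([0.5, 0.2]) + rng.standard_normal(n)
        X_all = pd.DataFrame(X, columns=["x1", "x2"])
        gspec = GPriorSpec(r=pd.DataFrame(1e12, index=X_all.columns, columns=["y1"]), mu=1.0)
        g_fit = best_subset(X_all, y, gspec, response="y1")
        o_fit = no_prior_baseline(X_all, y)
        assert g_fit.predictors == o_fit.predictors
        assert np.allclose(g_fit.fit.beta_tilde, o_fit.fit.beta_tilde, atol=1e-6)
        # E[BIC] vs plug-in BIC differ by the O(1) term n(ln(n/2) - psi(n/2))
        n_s = len(y)
        gap = (g_fit.fit.expected_bic - o_fit.fit.expected_bic) - n_s * (
            np.log(n_s / 2) - digamma(n_s / 2)
        )
        assert abs(gap) < 1e-4


class TestConfidenceScore:
    def test_single_predictor_equals_r2(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(100)
        y = 0.7 * x + rng.standard_normal(100)
        X_all = pd.DataFrame({"x1": x})
        fit = no_prior_baseline(X_all, y)
        scores = confidence_score(fit, X_all, y)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert scores["x1"] == pytest.approx(r2, abs=1e-10)

    def test_orthogonal_predictor_scores_zero(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        y = x1.copy()
        X_all = pd.DataFrame({"x1": x1, "x2": x2})
        gspec = GPriorSpec(r=pd.DataFrame(3.0, index=X_all.columns, columns=["y1"]), mu=1.0)
        fit = best_subset(X_all, y, gspec, response="y1", max_size=2)
        fit.predictors = ("x1", "x2")
        scores = confidence_score(fit, X_all, y)
        assert scores["x2"] == pytest.approx(0.0, abs=1e-10)

    def test_stronger_signal_scores_higher(self):
        rng = np.random.default_rng(19)
        n = 300
        x1, x2 = rng.standard_normal((2, n))
        y = 0.8 * x1 + 0.2 * x2 + rng.standard_normal(n)
        X_all = pd.DataFrame({"x1": x1, "x2": x2})
        fit = no_prior_baseline(X_all, y, max_size=2)
        scores = confidence_score(fit, X_all, y)
        assert scores["x1"] > scores["x2"]


class TestTuneMu:
    @staticmethod
    def _setup(seed=20):
        rng = np.random.default_rng(seed)
        n = 120
        X_all = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["x1", "x2", "x3"]
        )
        y1 = 0.8 * X_all["x1"].to_numpy() + rng.standard_normal(n)
        responses = pd.DataFrame({"s": range(n)}).T  # placeholder
        responses = pd.DataFrame([y1], index=["y1"], columns=X_all.index)
        r = pd.DataFrame(2.0, index=X_all.columns, columns=["y1"])
        return X_all, responses, r

    def test_identical_fits_return_smallest_mu(self):
        X_all, responses, r = self._setup()
        # both huge weights give the same subsets and the same paired p-values
        mu_star, table, _ = tune_mu(X_all, responses, r, [1e6, 2e6], B=50, seed=0)
        assert mu_star == 1e6
        assert table["meta_p"].nunique() == 1

    def test_single_subnetwork_meta_p_equals_own_p(self):
        X_all, responses, r = self._setup()
        mu_star, table, fits = tune_mu(X_all, responses, r, [1.0], B=99, seed=1)
        assert table.loc[1.0, "meta_p"] == pytest.approx(fits["y1"].correlation_p, rel=1e-9)


class TestRelatednessMatrix:
    def test_shape_and_values(self):
        pred = {"x1": ["a", "b"], "x2": ["c"]}
        resp = {"y1": ["d", "e"]}
        ppi = InteractionNetwork([("a", "d"), ("b", "e"), ("c", "d")])
        r = relatedness_matrix(pred, resp, ppi)
        assert r.loc["x1", "y1"] == pytest.approx(2 * 2 / 4)
        assert r.loc["x2", "y1"] == pytest.approx(2 * 1 / 3)
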
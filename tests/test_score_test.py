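"""Region score statistic, null eigenvalues, moments and orchestration."""

import numpy as np
import pytest

from famvc.kernels import burden_similarity, linear_similarity, SimilarityMatrix
from famvc.null_model import PolygenicModel, fit_null
from famvc.relatedness import RelatednessSet
from famvc.score_test import (moments, null_eigenvalues, score_statistic,
                              test_region)

from conftest import draw_mvn


def dense_reference(fit, Sd):
    """Dense-matrix oracle for T, eigenvalues and raw moments."""
    y = fit.model.y
    X = fit.model.X
    V = fit.V0
    Vi = np.linalg.inv(V)
    if fit.method == "REML":
        W = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
    else:
        W = Vi
    r = y - X @ fit.beta_hat
    T = 0.5 * r @ W @ Sd @ W @ r
    lam = np.linalg.eigvalsh(0.5 * np.linalg.cholesky(V).T @ W @ Sd @ W
                             @ np.linalg.cholesky(V))[::-1]
    mu = 0.5 * np.trace(W @ Sd)
    nu = 0.5 * np.trace(W @ Sd @ W @ Sd)
    return T, lam, mu, nu


@pytest.fixture
def fitted(mixed_relatedness):
    _, _, rel = mixed_relatedness
    rng = np.random.default_rng(21)
    y = draw_mvn(rel, 0.4, 0.6, rng)
    Z = rng.standard_normal((len(y), 25))
    return fit_null(y, rel=rel, method="reml"), linear_similarity(Z), Z


class TestScoreStatistic:
    def test_zero_residuals_give_zero(self):
        q = 30
        rel = RelatednessSet([f"U{i}" for i in range(q)], np.eye(q))
        rng = np.random.default_rng(1)
        y = rng.standard_normal(q)
        fit = fit_null(y, rel=rel)
        S = burden_similarity(np.zeros(q))  # S = 0 matrix
        T, U = score_statistic(None, None, fit, S)
        assert T == 0.0 and U == 0.0

    def test_identity_toy_closed_form(self):
        # V0 = I, X = intercept, S = I: T = 0.5 * sum((y - ybar)^2)
        y = np.array([1.0, -1.0, 2.0, -2.0])
        q = 4
        rel = RelatednessSet(list("abcd"), np.eye(q))
        fit = fit_null(y, rel=rel, method="ml")
        s2 = fit.sigma2_delta + fit.sigma2_eps
        S = SimilarityMatrix(kind="linear", n_variants=4, dense=np.eye(q))
        T, U = score_statistic(None, None, fit, S)
        # V0 = s2*I, so T = 0.5 * ||r||^2 / s2^2; scale back for the check
        assert T * s2 ** 2 == pytest.approx(0.5 * np.sum((y - y.mean()) ** 2))

    def test_matches_dense_oracle(self, fitted):
        fit, S, Z = fitted
        T, U = score_statistic(None, None, fit, S)
        T_o, lam_o, mu_o, nu_o = dense_reference(fit, S.matrix)
        assert T == pytest.approx(T_o, rel=1e-8)

    def test_ml_u_equals_t_minus_half_trace(self, mixed_relatedness):
        _, _, rel = mixed_relatedness
        rng = np.random.default_rng(2)
        y = draw_mvn(rel, 0.4, 0.6, rng)
        fit = fit_null(y, rel=rel, method="ml")
        Z = rng.standard_normal((len(y), 10))
        S = linear_similarity(Z)
        T, U = score_statistic(None, None, fit, S)
        Vi = np.linalg.inv(fit.V0)
        assert U == pytest.approx(T - 0.5 * np.trace(Vi @ S.matrix), rel=1e-8)


class TestEigenvaluesAndMoments:
    def test_identity_case_all_half(self):
        q = 12
        rel = RelatednessSet([f"U{i}" for i in range(q)], np.eye(q))
        rng = np.random.default_rng(3)
        y = rng.standard_normal(q)
        fit = fit_null(y, rel=rel, method="ml")
        s2 = fit.sigma2_delta + fit.sigma2_eps
        S = SimilarityMatrix(kind="linear", n_variants=q, dense=np.eye(q))
        lam = null_eigenvalues(fit, S)
        # V0 = s2 I  =>  eigenvalues all 1/(2 s2)
        np.testing.assert_allclose(lam, 0.5 / s2, rtol=1e-8)

    def test_rank_one_single_eigenvalue(self):
        q = 15
        rel = RelatednessSet([f"U{i}" for i in range(q)], np.eye(q))
        rng = np.random.default_rng(4)
        y = rng.standard_normal(q)
        z = rng.standard_normal(q)
        fit = fit_null(y, rel=rel, method="ml")
        lam = null_eigenvalues(fit, burden_similarity(z))
        assert lam.size == 1

    def test_matches_dense_eigensolver(self, fitted):
        fit, S, Z = fitted
        lam = null_eigenvalues(fit, S)
        _, lam_o, _, _ = dense_reference(fit, S.matrix)
        np.testing.assert_allclose(lam, lam_o[:lam.size], atol=1e-8)

    def test_truncation_returns_r_largest(self, fitted):
        fit, S, _ = fitted
        lam_all = null_eigenvalues(fit, S)
        lam_5 = null_eigenvalues(fit, S, r=5)
        np.testing.assert_allclose(lam_5, lam_all[:5])

    def test_trace_identities(self, fitted):
        # mu_T = sum(lambda); nu_T = 2 sum(lambda^2)
        fit, S, _ = fitted
        lam = null_eigenvalues(fit, S)
        mu, nu = moments(fit, S, correct="none")
        assert lam.sum() == pytest.approx(mu, rel=1e-8)
        assert 2 * (lam ** 2).sum() == pytest.approx(nu, rel=1e-8)

    def test_moments_match_dense_oracle(self, fitted):
        fit, S, _ = fitted
        mu, nu = moments(fit, S, correct="none")
        _, _, mu_o, nu_o = dense_reference(fit, S.matrix)
        assert mu == pytest.approx(mu_o, rel=1e-8)
        assert nu == pytest.approx(nu_o, rel=1e-8)

    def test_correction_reduces_variance_on_random_instances(self,
                                                             mixed_relatedness):
        _, _, rel = mixed_relatedness
        rng = np.random.default_rng(5)
        for method in ("ml", "reml"):
            for _ in range(20):
                y = draw_mvn(rel, 0.4, 0.6, rng)
                fit = fit_null(y, rel=rel, method=method)
                S = linear_similarity(rng.standard_normal((len(y), 8)))
                _, nu_raw = moments(fit, S, correct="none")
                _, nu_corr = moments(fit, S, correct="partial_information")
                assert nu_corr <= nu_raw + 1e-10

    def test_identity_a_falls_back_uncorrected(self):
        # A = I makes the nuisance information singular
        q = 40
        rel = RelatednessSet([f"U{i}" for i in range(q)], np.eye(q))
        rng = np.random.default_rng(6)
        y = rng.standard_normal(q)
        fit = fit_null(y, rel=rel, method="ml")
        S = linear_similarity(rng.standard_normal((q, 5)))
        mu_r, nu_r = moments(fit, S, correct="none")
        mu_c, nu_c = moments(fit, S, correct="partial_information")
        assert mu_c == mu_r
        assert 0 < nu_c <= nu_r + 1e-10


class TestTestRegion:
    def test_permutation_invariance(self, mixed_relatedness):
        _, _, rel = mixed_relatedness
        rng = np.random.default_rng(7)
        y = draw_mvn(rel, 0.4, 0.6, rng)
        Z = rng.standard_normal((len(y), 12))
        res = test_region(y, rel=rel, similarity=linear_similarity(Z),
                          p_methods=("davies",))
        perm = rng.permutation(len(y))
        rel_p = RelatednessSet([rel.samples[i] for i in perm],
                               rel.A.to_dense()[np.ix_(perm, perm)])
        res_p = test_region(y[perm], rel=rel_p,
                            similarity=linear_similarity(Z[perm]),
                            p_methods=("davies",))
        # block-structured vs dense A take different eigendecomposition
        # routes, so agreement is at optimizer tolerance rather than exact
        assert res_p.T == pytest.approx(res.T, rel=1e-5)
        assert res_p.p_values["davies"] == pytest.approx(
            res.p_values["davies"], abs=1e-6)

    def test_single_variant_davies_equals_exact_chi2(self, mixed_relatedness):
        from scipy import stats
        _, _, rel = mixed_relatedness
        rng = np.random.default_rng(8)
        y = draw_mvn(rel, 0.4, 0.6, rng)
        z = rng.standard_normal(len(y))
        res = test_region(y, rel=rel, similarity=burden_similarity(z),
                          p_methods=("davies",))
        lam = res.eigenvalues[0]
        assert res.p_values["davies"] == pytest.approx(
            float(stats.chi2.sf(res.T / lam, 1)), abs=1e-6)

    def test_p_monotone_in_statistic(self, fitted):
        fit, S, _ = fitted
        lam = null_eigenvalues(fit, S)
        from famvc.quadform import pvalue_davies
        ps = [pvalue_davies(t, lam) for t in np.linspace(1, 60, 20)]
        assert np.all(np.diff(ps) <= 1e-12)

    def test_null_pvalues_roughly_uniform(self, mixed_relatedness):
        # small end-to-end calibration check (the full one runs in acceptance)
        from scipy import stats
        _, _, rel = mixed_relatedness
        rng = np.random.default_rng(9)
        pvals = []
        for k in range(200):
            y = draw_mvn(rel, 0.4, 0.6, rng)
            Z = rng.binomial(2, 0.2, size=(len(y), 10)).astype(float)
            Z = Z - Z.mean(axis=0)
            res = test_region(y, rel=rel, similarity=linear_similarity(Z),
                              p_methods=("davies",))
            pvals.append(res.p_values["davies"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_result_serializes(self, fitted):
        fit, S, _ = fitted
        res = test_region(None, rel=fit.model.rel, similarity=S, null_fit=fit,
                          p_methods=("davies", "liu"))
        d = res.to_dict()
        assert set(d["p_values"]) == {"davies", "liu"}
        assert "T" in res.summary() or "T statistic" in res.summary()
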
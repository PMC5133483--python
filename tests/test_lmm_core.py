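import numpy as np
import pytest

import fameqtl as fq
from fameqtl.lmm_core import (LmmFit, _neg2_reml, eigen_kinship,
                              fit_rotated_fast, normality_scan,
                              pca_covariates, reml_fit, wald_p)
from fameqtl.relatedness import KinshipMatrix


def dense_reml_loglik(y, X, V):
    """Brute-force multivariate-normal REML objective on a dense covariance."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_A = np.linalg.slogdet(A)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_A + r @ Vi @ r)


@pytest.fixture(scope="module")
def toy12():
    """n=12 mixed-model problem with an interior variance-ratio optimum."""
    rng = np.random.default_rng(7)
    ped = fq.simulate_pedigree(2, fq.PedigreeStructure([4]), rng)
    kin = fq.kinship_from_pedigree(ped)
    n = kin.n
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    L = np.linalg.cholesky(kin.additive_relationship() + 1e-10 * np.eye(n))
    y = X @ [1.0, 0.5, -0.3] + 1.5 * (L @ rng.normal(size=n)) \
        + 0.5 * rng.normal(size=n)
    return y, X, kin


class TestRemlFit:
    def test_noiseless_exact_recovery(self, kin12):
        n = kin12.n
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([2.0, -1.0])
        fit = reml_fit(X @ beta_true, X, K=kin12)
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-8)
        assert fit.sigma_e2 < 1e-10

    def test_identity_kinship_collapses_to_ols(self):
        n = 40
        rng = np.random.default_rng(1)
        kin = KinshipMatrix([f"s{i}" for i in range(n)], 0.5 * np.eye(n),
                            [(i, i + 1) for i in range(n)])
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, 3.0] + rng.normal(size=n)
        fit = reml_fit(y, X, K=kin)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    def test_matches_dense_grid_oracle(self, toy12):
        """REML loglik within 1e-6 of the dense objective's 1-D optimum, and
        beta equal to closed-form GLS at the fitted variances."""
        y, X, kin = toy12
        fit = reml_fit(y, X, K=kin)
        assert not fit.boundary
        K = kin.additive_relationship()
        n = kin.n
        # dense profile over the variance ratio on a fine log grid
        best = -np.inf
        for lg in np.linspace(np.log(1e-4), np.log(1e4), 4001):
            g = np.exp(lg)
            V = g * K + np.eye(n)  # up to the profiled sigma_e2 scale
            # profile sigma_e2 in the dense formula
            Vi = np.linalg.inv(V)
            A = X.T @ Vi @ X
            beta = np.linalg.solve(A, X.T @ Vi @ y)
            r = y - X @ beta
            s2 = (r @ Vi @ r) / (n - X.shape[1])
            ll = dense_reml_loglik(y, X, s2 * V)
            best = max(best, ll)
        assert fit.loglik_reml == pytest.approx(best, abs=1e-6)
        V = fit.sigma_g2 * K + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, gls, atol=1e-8)

    def test_optimum_beats_random_ratios(self, toy12):
        y, X, kin = toy12
        eig = eigen_kinship(kin)
        yr, Xr = eig.rotate(y), eig.rotate(X)
        fit = reml_fit(yr, Xr, eig=eig, rotated=True)
        obj_opt = -2.0 * fit.loglik_reml
        rng = np.random.default_rng(9)
        for lg in rng.uniform(np.log(1e-6), np.log(1e6), 50):
            assert _neg2_reml(lg, eig.lam, Xr, yr) >= obj_opt - 1e-8

    def test_sample_permutation_invariance(self, toy12):
        y, X, kin = toy12
        fit = reml_fit(y, X, K=kin)
        rng = np.random.default_rng(4)
        perm = rng.permutation(kin.n)
        kin_p = KinshipMatrix([kin.sample_ids[i] for i in perm],
                              kin.phi[np.ix_(perm, perm)],
                              [(0, kin.n)])
        fit_p = reml_fit(y[perm], X[perm], K=kin_p)
        np.testing.assert_allclose(fit_p.beta, fit.beta, atol=1e-8)
        assert fit_p.loglik_reml == pytest.approx(fit.loglik_reml, abs=1e-8)
        assert fit_p.sigma_g2 == pytest.approx(fit.sigma_g2, rel=1e-5, abs=1e-10)

    def test_rank_deficient_names_columns(self, kin12):
        n = kin12.n
        x = np.random.default_rng(0).normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="dup"):
            reml_fit(np.zeros(n), X, K=kin12,
                     names=["intercept", "x", "dup"])

    def test_fast_path_agrees_with_full_fit(self, toy12):
        y, X, kin = toy12
        eig = eigen_kinship(kin)
        yr, Xr = eig.rotate(y), eig.rotate(X)
        fit = reml_fit(yr, Xr, eig=eig, rotated=True)
        b, se, gamma = fit_rotated_fast(yr, Xr, eig.lam)
        assert b == pytest.approx(fit.beta[-1], abs=1e-10)
        assert se == pytest.approx(fit.se[-1], abs=1e-10)


class TestWald:
    def make_fit(self, beta, se):
        return LmmFit(beta=np.array([beta]), se=np.array([se]), names=["snp"],
                      sigma_g2=1.0, sigma_e2=1.0, loglik_reml=0.0,
                      converged=True)

    def test_zero_effect_p_one(self):
        assert wald_p(self.make_fit(0.0, 1.0), "snp") == pytest.approx(1.0)

    def test_z_1959964_p_005(self):
        assert wald_p(self.make_fit(1.959964, 1.0), "snp") == \
            pytest.approx(0.05, abs=1e-6)

    def test_null_p_uniform(self):
        """Wald p of a null SNP coefficient is uniform across simulations."""
        from scipy.stats import kstest

        ped = fq.simulate_pedigree(30, fq.PedigreeStructure([4]), 0)
        kin = fq.kinship_from_pedigree(ped)
        eig = eigen_kinship(kin)
        n = kin.n
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(kin.additive_relationship() + 1e-10 * np.eye(n))
        Xr = eig.rotate(np.ones((n, 1)))
        pvals = []
        for _ in range(400):
            y = 0.7 * (L @ rng.normal(size=n)) + 0.7 * rng.normal(size=n)
            s = rng.binomial(2, 0.3, n).astype(float)
            X = np.column_stack([Xr, eig.rotate(s)])
            b, se, _ = fit_rotated_fast(eig.rotate(y), X, eig.lam)
            from scipy.stats import chi2
            pvals.append(chi2.sf((b / se) ** 2, 1))
        assert kstest(pvals, "uniform").pvalue > 0.01
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= frac <= 0.08


class TestEstimateH2:
    def test_clone_duplication_boundary(self, kin12):
        """Perfectly heritable signal drives h2 to the upper boundary."""
        n = kin12.n
        L = np.linalg.cholesky(kin12.additive_relationship() + 1e-10 * np.eye(n))
        y = L @ np.random.default_rng(2).normal(size=n)
        h2 = fq.estimate_h2(y, np.ones((n, 1)), K=kin12)
        assert h2 > 0.95

    def test_moderate_h2_recovered_in_mean(self):
        from fameqtl.synthetic_data import ExpressionParams, _make_study

        st = _make_study(13, 40, 4, 50, ExpressionParams(
            n_probes=300, causal_fraction=0.0, h2_fixed=0.5, batch_sd=0.0))
        eig = eigen_kinship(st.kinship)
        X = st.covariates.design_matrix(st.kinship.sample_ids,
                                        ("age", "sex", "smoking"))
        Xr = eig.rotate(X)
        vals = [reml_fit(eig.rotate(y), Xr, eig=eig, rotated=True).h2
                for y in st.expression.values]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.06)


class TestPca:
    def test_recovers_planted_batch_factor(self):
        rng = np.random.default_rng(5)
        n, m = 60, 150
        factor = rng.normal(size=n)
        load = rng.normal(size=m)
        Y = np.outer(load, factor) + 0.05 * rng.normal(size=(m, n))
        expr = fq.ExpressionMatrix([f"p{i}" for i in range(m)],
                                   [f"s{i}" for i in range(n)], Y)
        scores = pca_covariates(expr, k=2)
        r = np.corrcoef(scores[:, 0], factor)[0, 1]
        assert abs(r) > 0.99

    def test_scores_orthogonal(self, small_study):
        scores = pca_covariates(small_study.expression, k=2)
        dot = scores[:, 0] @ scores[:, 1]
        assert abs(dot) < 1e-8 * np.linalg.norm(scores[:, 0]) * \
            np.linalg.norm(scores[:, 1])

    def test_sample_permutation_equivariance(self, small_study):
        expr = small_study.expression
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(expr.sample_ids))
        expr_p = fq.ExpressionMatrix(expr.probe_ids,
                                     [expr.sample_ids[i] for i in perm],
                                     expr.values[:, perm])
        s1 = pca_covariates(expr, k=2)
        s2 = pca_covariates(expr_p, k=2)
        np.testing.assert_allclose(s2, s1[perm], atol=1e-8)

    def test_constant_matrix_errors(self):
        expr = fq.ExpressionMatrix(["p1", "p2"], ["a", "b", "c", "d"],
                                   np.ones((2, 4)))
        with pytest.raises(ValueError, match="constant"):
            pca_covariates(expr)


class TestNormalityScan:
    def test_gaussian_probes_rarely_flagged(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(400, 267))
        expr = fq.ExpressionMatrix([f"p{i}" for i in range(400)],
                                   [f"s{i}" for i in range(267)], Y)
        res = normality_scan(expr)
        assert res["bonferroni_significant"].sum() <= 1

    def test_exponential_probe_flagged(self):
        rng = np.random.default_rng(9)
        Y = np.vstack([rng.normal(size=(99, 267)),
                       rng.exponential(size=(1, 267))])
        expr = fq.ExpressionMatrix([f"p{i}" for i in range(100)],
                                   [f"s{i}" for i in range(267)], Y)
        res = normality_scan(expr)
        assert bool(res["bonferroni_significant"].iloc[-1])

    def test_single_probe_threshold(self):
        rng = np.random.default_rng(10)
        expr = fq.ExpressionMatrix(["p"], [f"s{i}" for i in range(50)],
                                   rng.exponential(size=(1, 50)))
        res = normality_scan(expr)
        # Bonferroni threshold with one probe is plain 0.05
        assert bool(res["bonferroni_significant"].iloc[0]) == \
            (res["shapiro_p"].iloc[0] < 0.05)

    def test_constant_probe_excluded(self):
        rng = np.random.default_rng(11)
        Y = np.vstack([np.ones((1, 30)), rng.normal(size=(3, 30))])
        expr = fq.ExpressionMatrix(list("abcd"), [f"s{i}" for i in range(30)], Y)
        res = normality_scan(expr)
        assert not bool(res["testable"].iloc[0])
        assert np.isnan(res["shapiro_p"].iloc[0])
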
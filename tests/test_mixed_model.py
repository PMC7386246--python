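"""REML, BLUP and association scans against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from agblup.kinship import standard_kinship
from agblup.mixed_model import (
    KinshipEig,
    blup_predict,
    fit_variance_components,
    glm_scan,
    mlm_scan,
    _reml_neg_ll,
)
from agblup.simulate import SimScenario, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="module")
def reml_instance():
    g = simulate_genotypes(150, 400, seed=41)
    y, tbv, _ = simulate_phenotypes(g, SimScenario.polygenic(0.5, 400), seed=42)
    K = standard_kinship(g).values
    return y.values, K


class TestRemL:
    def test_optimum_beats_dense_h2_grid(self, reml_instance):
        y, K = reml_instance
        vc = fit_variance_components(y, K)
        eig = KinshipEig(K)
        ys = eig.U.T @ y
        Xs = eig.U.T @ np.ones((y.size, 1))
        _, ldXX = np.linalg.slogdet(np.full((1, 1), float(y.size)))
        grid = np.linspace(1e-5, 1 - 1e-5, 50)
        grid_ll = [-_reml_neg_ll(h, eig.d, ys, Xs, ldXX) for h in grid]
        assert vc.log_likelihood >= max(grid_ll) - 1e-9

    def test_phenotype_in_fixed_space_returns_zero_variances(self, reml_instance):
        _, K = reml_instance
        X = np.arange(K.shape[0], dtype=float)
        with pytest.warns(UserWarning, match="column space"):
            vc = fit_variance_components(3.0 + 2.0 * X, K, X=X)
        assert vc.sigma_g2 == 0.0 and vc.sigma_e2 == 0.0

    def test_invariant_to_individual_permutation(self, reml_instance):
        y, K = reml_instance
        perm = np.random.default_rng(0).permutation(y.size)
        vc1 = fit_variance_components(y, K)
        vc2 = fit_variance_components(y[perm], K[np.ix_(perm, perm)])
        assert vc1.h2 == pytest.approx(vc2.h2, abs=1e-6)

    def test_zero_phenotypic_variance_rejected(self, reml_instance):
        _, K = reml_instance
        with pytest.raises(ValueError, match="variance"):
            fit_variance_components(np.ones(K.shape[0]), K)


class TestBlup:
    def test_matches_henderson_mixed_model_equations(self):
        g = simulate_genotypes(100, 300, seed=51)
        y, _, _ = simulate_phenotypes(g, SimScenario.polygenic(0.4, 300), seed=52)
        K = standard_kinship(g).values + 1e-6 * np.eye(100)
        vc = fit_variance_components(y.values, K)
        res = blup_predict(y.values, K, np.arange(100), vc)
        X = np.ones((100, 1))
        lam = vc.sigma_e2 / vc.sigma_g2
        lhs = np.block(
            [[X.T @ X, X.T], [X, np.eye(100) + lam * np.linalg.inv(K)]]
        )
        rhs = np.concatenate([X.T @ y.values, y.values])
        sol = np.linalg.solve(lhs, rhs)
        assert abs(sol[0] - res.b[0]) < 1e-8
        np.testing.assert_allclose(res.random_part, sol[1:], atol=1e-8)

    def test_zero_genetic_variance_gives_zero_random_part(self, reml_instance):
        y, K = reml_instance
        from agblup.mixed_model import VarianceComponents

        vc = VarianceComponents(0.0, float(np.var(y)), 0.0)
        res = blup_predict(y, K, np.arange(y.size), vc)
        np.testing.assert_array_equal(res.random_part, 0.0)

    def test_pseudo_qtn_prediction_equals_residual_identity(self):
        # fitting one dosage column as a fixed covariate and predicting
        # Qq + BLUP(y - Qq residuals) must match the joint solve
        g = simulate_genotypes(80, 200, seed=61)
        y, _, _ = simulate_phenotypes(g, SimScenario.major_genes(0.6, 3), seed=62)
        K = standard_kinship(g).values
        vc = fit_variance_components(y.values, K, X=g.values[:, [0]])
        obs = np.arange(80)
        joint = blup_predict(y.values, K, obs, vc, Q=g.values[:, [0]])
        resid = y.values - g.values[:, [0]] @ joint.q - joint.b[0]
        eig = KinshipEig(K)
        w = vc.sigma_g2 * eig.d + vc.sigma_e2
        manual_random = vc.sigma_g2 * (K @ (eig.U @ ((eig.U.T @ resid) / w)))
        np.testing.assert_allclose(
            joint.mu, g.values[:, [0]] @ joint.q + manual_random, atol=1e-10
        )

    def test_shift_equivariance(self, reml_instance):
        y, K = reml_instance
        vc = fit_variance_components(y, K)
        r1 = blup_predict(y, K, np.arange(y.size), vc)
        r2 = blup_predict(y + 5.0, K, np.arange(y.size), vc)
        assert r2.b[0] - r1.b[0] == pytest.approx(5.0, abs=1e-8)
        np.testing.assert_allclose(r1.mu, r2.mu, atol=1e-8)

    def test_unphenotyped_individuals_receive_predictions(self):
        g = simulate_genotypes(60, 200, seed=71)
        y, tbv, _ = simulate_phenotypes(g, SimScenario.polygenic(0.8, 200), seed=72)
        K = standard_kinship(g).values
        obs = np.arange(40)  # last 20 unphenotyped
        vc = fit_variance_components(y.values[obs], K[np.ix_(obs, obs)])
        res = blup_predict(y.values[obs], K, obs, vc)
        assert res.mu.shape == (60,)
        assert np.corrcoef(res.mu[40:], tbv[40:])[0, 1] > 0.1


class TestGlmScan:
    def test_perfect_association_underflows(self, rng):
        G = rng.integers(0, 3, (60, 5)).astype(float)
        res = glm_scan(G[:, 2].copy(), G)
        assert res.p_values[2] < 1e-20

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        y = rng.standard_normal(50)
        G = rng.integers(0, 3, (50, 8)).astype(float)
        cov = rng.standard_normal(50)
        res = glm_scan(y, G, covariates=cov)
        for j in range(8):
            X = sm.add_constant(np.column_stack([cov, G[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.p_values[j] == pytest.approx(fit.pvalues[-1], abs=1e-10)
            assert res.effects[j] == pytest.approx(fit.params[-1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        y = rng.standard_normal(300)
        G = rng.binomial(2, 0.3, (300, 2000)).astype(float)
        res = glm_scan(y, G)
        assert stats.kstest(res.p_values, "uniform").pvalue > 0.01

    def test_constant_marker_flagged_degenerate(self, rng):
        G = np.column_stack([np.full(30, 1.0), rng.integers(0, 3, 30).astype(float)])
        res = glm_scan(rng.standard_normal(30), G)
        assert res.degenerate[0] and res.p_values[0] == 1.0


class TestMlmScan:
    def test_identity_kinship_matches_glm_to_three_figures(self, rng):
        n = 500
        y = rng.standard_normal(n)
        G = rng.binomial(2, 0.4, (n, 40)).astype(float)
        glm = glm_scan(y, G)
        mlm = mlm_scan(y, G, np.eye(n))
        np.testing.assert_allclose(mlm.p_values, glm.p_values, rtol=5e-3)

    def test_reduces_inflation_under_stratification(self, rng):
        # two subpopulations with different allele frequencies and a mean shift
        n = 400
        pop = np.repeat([0, 1], n // 2)
        freqs = np.where(pop[:, None] == 0, 0.2, 0.6)
        G = rng.binomial(2, freqs, (n, 600)).astype(float)
        y = pop * 1.0 + rng.standard_normal(n) * 0.5
        K = standard_kinship(_wrap(G)).values
        glm = glm_scan(y, G)
        mlm = mlm_scan(y, G, K)

        def inflation(p):
            chi2 = stats.chi2.isf(p, 1)
            return np.median(chi2) / stats.chi2.median(1)

        assert abs(inflation(mlm.p_values) - 1) < abs(inflation(glm.p_values) - 1)

    def test_zero_variance_marker_degenerate(self, rng):
        n = 50
        G = np.column_stack([np.zeros(n), rng.integers(0, 3, n).astype(float)])
        res = mlm_scan(rng.standard_normal(n), G, np.eye(n))
        assert res.degenerate[0] and res.p_values[0] == 1.0


def _wrap(G):
    from conftest import make_genotypes

    return make_genotypes(G)
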
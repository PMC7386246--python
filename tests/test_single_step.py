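"""Pedigree relationships and single-step matrix construction."""

import numpy as np
import pytest

from agblup.genotype_io import Pedigree, PhenotypeVector
from agblup.kinship import standard_kinship
from agblup.mixed_model import blup_predict, fit_variance_components
from agblup.single_step import (
    HMatrixConfig,
    blend_scale_g,
    h_matrix,
    h_matrix_inverse,
    pedigree_a_matrix,
    pedigree_blup,
    ss_predict,
)
from agblup.simulate import SimScenario, simulate_pedigree_population


def _drop_monomorphic(g):
    f = g.allele_freq
    return g.subset_markers(np.flatnonzero((f > 0) & (f < 1)))


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(["a", "b"], ["0", "0"], ["0", "0"])
        np.testing.assert_array_equal(pedigree_a_matrix(ped), np.eye(2))

    def test_parent_offspring_half(self):
        ped = Pedigree(["a", "b", "kid"], ["0", "0", "a"], ["0", "0", "b"])
        A = pedigree_a_matrix(ped)
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5 and A[2, 2] == 1.0

    def test_full_sib_mating_produces_inbreeding(self):
        ped = Pedigree(
            ["a", "b", "s1", "s2", "kid"],
            ["0", "0", "a", "a", "s1"],
            ["0", "0", "b", "b", "s2"],
        )
        A = pedigree_a_matrix(ped)
        assert A[2, 3] == 0.5  # full sibs
        assert A[4, 4] == pytest.approx(1.25)  # F = 0.25 from full-sib mating

    def test_matches_gene_dropping_monte_carlo(self):
        # gene dropping: drop two independent alleles through the pedigree
        # and estimate 2 * kinship by allele-identity probability
        rng = np.random.default_rng(0)
        pop = simulate_pedigree_population(
            10, 3, 2, m=10, seed=1, scenario=SimScenario.gamma_qtl_trait(0.5, n_qtl=3)
        )
        ped = pop.pedigree
        A = pedigree_a_matrix(ped)
        n = len(ped)
        idx = {iid: i for i, iid in enumerate(ped.individuals)}
        order = ped.topological_order()
        drops = 100_000
        alleles = np.empty((n, 2, drops), dtype=np.int64)
        counter = 0
        for i in order:
            for pslot, parent in enumerate((ped.sires[i], ped.dams[i])):
                if parent == "0":
                    alleles[i, pslot] = np.arange(counter * drops, (counter + 1) * drops)
                    counter += 1
                else:
                    p = idx[parent]
                    pick = rng.integers(0, 2, drops)
                    alleles[i, pslot] = alleles[p, pick, np.arange(drops)]
        # estimate A for a handful of random pairs
        pairs = [(0, 1), (n - 1, n - 2), (0, n - 1), (n // 2, n - 1)]
        for i, j in pairs:
            ident = np.mean(
                [
                    (alleles[i, a] == alleles[j, b]).mean()
                    for a in range(2)
                    for b in range(2)
                ]
            )
            est = 2 * ident if i != j else 1 + ident
            assert A[i, j] == pytest.approx(est, abs=0.02)


class TestBlendScale:
    def test_full_blend_returns_a22(self, rng):
        G = rng.standard_normal((6, 6))
        G = G @ G.T
        A22 = np.eye(6) * 1.1
        out = blend_scale_g(G, A22, HMatrixConfig(blend_weight=1.0))
        np.testing.assert_allclose(out, A22)

    def test_no_blend_scale_matched_g_unchanged(self, rng):
        G = rng.standard_normal((5, 5))
        G = G @ G.T
        cfg = HMatrixConfig(blend_weight=0.0)
        out1 = blend_scale_g(G, G, cfg)  # already on target scale
        np.testing.assert_allclose(out1, G, atol=1e-10)

    def test_moment_matching_arithmetic(self, rng):
        G = rng.standard_normal((8, 8))
        G = G @ G.T
        A22 = rng.standard_normal((8, 8))
        A22 = A22 @ A22.T / 8 + np.eye(8)
        w = 0.05
        out = blend_scale_g(G, A22, HMatrixConfig(blend_weight=w))
        off = ~np.eye(8, dtype=bool)
        # after matching, diag/offdiag means are convex combinations
        assert np.diag(out).mean() == pytest.approx(np.diag(A22).mean(), abs=1e-10)
        assert out[off].mean() == pytest.approx(A22[off].mean(), abs=1e-10)

    def test_constant_g_rejected(self):
        with pytest.raises(ValueError, match="unsolvable"):
            blend_scale_g(np.ones((4, 4)), np.eye(4))


class TestHMatrix:
    def test_no_genotyped_individuals_reduces_to_a(self):
        pop = simulate_pedigree_population(8, 3, 2, m=50, seed=3)
        A = pedigree_a_matrix(pop.pedigree)
        Hinv = h_matrix_inverse(A, np.empty((0, 0)), np.empty((0, 0)), np.array([], int))
        np.testing.assert_allclose(Hinv, np.linalg.inv(A), atol=1e-8)

    def test_all_genotyped_with_g_equal_a_reduces_to_a(self):
        pop = simulate_pedigree_population(8, 2, 2, m=50, seed=4)
        A = pedigree_a_matrix(pop.pedigree)
        idx = np.arange(A.shape[0])
        Hinv = h_matrix_inverse(A, A, A, idx)
        np.testing.assert_allclose(Hinv, np.linalg.inv(A), atol=1e-8)

    def test_inverse_identity_against_direct_construction(self, rng):
        pop = simulate_pedigree_population(12, 3, 2, m=600, seed=5)
        A = pedigree_a_matrix(pop.pedigree)
        n = A.shape[0]
        geno = np.sort(rng.choice(n, 15, replace=False))
        g = _drop_monomorphic(pop.genotypes.subset_individuals(geno))
        G = standard_kinship(g).values
        A22 = A[np.ix_(geno, geno)]
        G_adj = blend_scale_g(G, A22)
        H = h_matrix(A, A22, G_adj, geno)
        Hinv = h_matrix_inverse(A, A22, G_adj, geno)
        np.testing.assert_allclose(np.linalg.inv(Hinv), H, atol=1e-8)

    def test_h_positive_semidefinite(self, rng):
        pop = simulate_pedigree_population(10, 3, 2, m=400, seed=6)
        A = pedigree_a_matrix(pop.pedigree)
        geno = np.sort(rng.choice(A.shape[0], 12, replace=False))
        g = _drop_monomorphic(pop.genotypes.subset_individuals(geno))
        G = standard_kinship(g).values
        A22 = A[np.ix_(geno, geno)]
        H = h_matrix(A, A22, blend_scale_g(G, A22), geno)
        assert np.linalg.eigvalsh(A).min() > -1e-8
        assert np.linalg.eigvalsh(H).min() > -1e-8


class TestSsPredict:
    def test_pedigree_only_equals_pblup(self):
        pop = simulate_pedigree_population(20, 3, 2, m=100, seed=7)
        res1 = ss_predict(pop.phenotype, pop.pedigree, None)
        res2 = pedigree_blup(pop.phenotype, pop.pedigree)
        np.testing.assert_allclose(res1.mu, res2.mu)

    def test_all_genotyped_no_blend_matches_gblup(self):
        pop = simulate_pedigree_population(30, 2, 2, m=800, seed=8)
        g = _drop_monomorphic(pop.genotypes)
        cfg = HMatrixConfig(blend_weight=0.0, scale_adjust=True)
        res_ss = ss_predict(pop.phenotype, pop.pedigree, g, cfg=cfg)
        # direct genomic BLUP on the scale-adjusted G
        A = pedigree_a_matrix(pop.pedigree)
        G_adj = blend_scale_g(standard_kinship(g).values, A, cfg)
        obs = np.flatnonzero(pop.phenotype.observed)
        vc = fit_variance_components(pop.phenotype.values[obs], G_adj[np.ix_(obs, obs)])
        res_g = blup_predict(pop.phenotype.values[obs], G_adj, obs, vc)
        np.testing.assert_allclose(res_ss.mu, res_g.mu, atol=1e-6)

    def test_predictions_for_every_pedigree_individual(self):
        pop = simulate_pedigree_population(20, 3, 2, m=300, seed=9)
        n = len(pop.pedigree)
        geno = np.arange(n // 2)
        g = _drop_monomorphic(pop.genotypes.subset_individuals(geno))
        yv = pop.phenotype.values.copy()
        yv[-10:] = np.nan
        res = ss_predict(PhenotypeVector(yv), pop.pedigree, g)
        assert res.mu.shape == (n,)
        assert np.isfinite(res.mu).all()
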
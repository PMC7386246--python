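"""Genotype file handling: PLINK round-trips, QC filters, imputation."""

import numpy as np
import pytest
from scipy import stats

from agblup.genotype_io import (
    EmptyPanelError,
    FormatError,
    Pedigree,
    PhenotypeVector,
    hwe_pvalues,
    impute_missing,
    qc_filter,
    read_pedigree,
    read_phenotype,
    read_plink,
    write_plink,
)
from agblup.simulate import simulate_genotypes

from conftest import make_genotypes


class TestPlinkRoundTrip:
    def test_handcrafted_matrix_round_trips_exactly(self, tmp_path):
        vals = np.array([[0.0, 1.0, 2.0], [2.0, np.nan, 0.0]])
        g = make_genotypes(vals)
        write_plink(g, tmp_path / "toy")
        back, fam = read_plink(tmp_path / "toy")
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(vals))
        np.testing.assert_array_equal(back.values[~np.isnan(vals)], vals[~np.isnan(vals)])
        assert back.individual_ids == g.individual_ids
        assert list(back.markers["id"]) == list(g.markers["id"])

    def test_all_missing_panel_reads_back_as_all_missing(self, tmp_path):
        g = make_genotypes(np.full((3, 2), np.nan))
        write_plink(g, tmp_path / "miss")
        back, _ = read_plink(tmp_path / "miss")
        assert np.isnan(back.values).all()
        assert np.isnan(back.allele_freq).all()

    @pytest.mark.parametrize("n", [50, 53])  # 53 exercises byte padding
    def test_random_matrix_bitwise_round_trip(self, tmp_path, n):
        g = simulate_genotypes(n, 200, seed=5)
        write_plink(g, tmp_path / "rt")
        back, _ = read_plink(tmp_path / "rt")
        np.testing.assert_array_equal(back.values, g.values)

    def test_bad_magic_bytes_rejected(self, tmp_path):
        g = make_genotypes(np.zeros((2, 2)))
        write_plink(g, tmp_path / "bad")
        raw = (tmp_path / "bad.bed").read_bytes()
        (tmp_path / "bad.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(FormatError, match="magic"):
            read_plink(tmp_path / "bad")

    def test_truncated_bed_rejected(self, tmp_path):
        g = simulate_genotypes(10, 20, seed=1)
        write_plink(g, tmp_path / "tr")
        raw = (tmp_path / "tr.bed").read_bytes()
        (tmp_path / "tr.bed").write_bytes(raw[:-3])
        with pytest.raises(FormatError, match="truncat"):
            read_plink(tmp_path / "tr")


class TestQcFilter:
    def test_monomorphic_marker_removed(self):
        g = make_genotypes(np.array([[0.0, 1], [0, 0], [0, 1], [0, 2]]))
        out = qc_filter(g, maf_min=0.01, cr_min=0.0, hwe_p_min=0.0)
        assert list(out.markers["id"]) == ["M0001"]

    def test_low_call_rate_marker_removed(self):
        vals = np.ones((10, 2))
        vals[:5, :] = 0.0
        vals[0, 0] = np.nan  # 10% missing on marker 0
        g = make_genotypes(vals)
        out = qc_filter(g, maf_min=0.0, cr_min=0.95, hwe_p_min=0.0)
        assert list(out.markers["id"]) == ["M0001"]

    def test_survivors_match_bruteforce_per_marker_check(self):
        rng = np.random.default_rng(3)
        g0 = simulate_genotypes(120, 500, maf_range=(0.01, 0.5), seed=33)
        vals = g0.values.copy()
        # plant missingness and rare-allele violations
        vals[rng.random(vals.shape) < 0.03] = np.nan
        vals[:, :20] = 0.0
        vals[0, :20] = 1.0
        g = make_genotypes(vals)
        maf_min, cr_min, hwe_min = 0.05, 0.97, 0.01
        out = qc_filter(g, maf_min, cr_min, hwe_min)

        hwe = hwe_pvalues(g)
        survivors = []
        for k in range(g.n_markers):  # brute-force re-check, one marker at a time
            col = vals[:, k]
            ok = ~np.isnan(col)
            cr = ok.mean()
            p = col[ok].mean() / 2 if ok.any() else np.nan
            maf = min(p, 1 - p) if np.isfinite(p) else np.nan
            if np.isfinite(maf) and maf >= maf_min and cr >= cr_min and hwe[k] >= hwe_min:
                survivors.append(f"M{k:04d}")
        assert list(out.markers["id"]) == survivors

    def test_filter_is_idempotent(self):
        g = simulate_genotypes(100, 300, maf_range=(0.02, 0.5), seed=9)
        once = qc_filter(g, 0.05, 0.95, 0.05)
        twice = qc_filter(once, 0.05, 0.95, 0.05)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_everything_removed_raises(self):
        g = make_genotypes(np.zeros((5, 3)))
        with pytest.raises(EmptyPanelError):
            qc_filter(g)


class TestImputeMissing:
    def test_column_mean_fill(self):
        g = make_genotypes(np.array([[0.0], [np.nan], [2.0]]))
        out = impute_missing(g)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 1.0, 2.0])

    def test_complete_matrix_unchanged(self, small_panel):
        out = impute_missing(small_panel)
        np.testing.assert_array_equal(out.values, small_panel.values)

    def test_allele_frequencies_preserved_exactly(self):
        rng = np.random.default_rng(17)
        g0 = simulate_genotypes(80, 150, seed=8)
        vals = g0.values.copy()
        vals[rng.random(vals.shape) < 0.2] = np.nan
        g = make_genotypes(vals)
        before = g.allele_freq
        after = impute_missing(g).allele_freq
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_fully_missing_marker_raises(self):
        g = make_genotypes(np.array([[np.nan, 1.0], [np.nan, 2.0]]))
        with pytest.raises(ValueError, match="all calls missing"):
            impute_missing(g)


class TestHwe:
    def test_hwe_proportions_not_rejected_and_excess_hets_rejected(self):
        rng = np.random.default_rng(4)
        p = 0.4
        geno = rng.binomial(1, p, (2000, 1)) + rng.binomial(1, p, (2000, 1))
        ok = make_genotypes(geno.astype(float))
        assert hwe_pvalues(ok)[0] > 0.01
        bad = make_genotypes(np.ones((2000, 1)))  # all heterozygous
        assert hwe_pvalues(bad)[0] < 1e-10


class TestTables:
    def test_phenotype_reorders_by_id_with_missing(self, tmp_path):
        (tmp_path / "ph.txt").write_text("b 2.5\na NA\nc 1.0\n")
        y = read_phenotype(tmp_path / "ph.txt", ["a", "b", "c", "d"])
        np.testing.assert_array_equal(np.isnan(y.values), [True, False, False, True])
        assert y.values[1] == 2.5 and y.values[2] == 1.0

    def test_binary_detection(self):
        assert PhenotypeVector(np.array([0.0, 1.0, np.nan])).is_binary
        assert not PhenotypeVector(np.array([1.0, 2.0, 3.0, 4.0])).is_binary

    def test_pedigree_topological_order_and_cycle_detection(self, tmp_path):
        (tmp_path / "ped.txt").write_text("kid pa ma\npa 0 0\nma 0 0\n")
        ped = read_pedigree(tmp_path / "ped.txt")
        order = ped.topological_order()
        names = [ped.individuals[i] for i in order]
        assert names.index("kid") > names.index("pa")
        assert names.index("kid") > names.index("ma")
        cyc = Pedigree(["x", "y"], ["y", "x"], ["0", "0"])
        with pytest.raises(ValueError, match="cyclic"):
            cyc.topological_order()
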
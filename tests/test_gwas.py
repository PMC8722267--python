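"""Genotype QC, GRM, association model, LD, regions and inflation factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from littervar.errors import ConfigurationError, InputError
from littervar.gwas import (
    GenotypeMatrix,
    GrmMatrix,
    compute_grm,
    define_vqtl_regions,
    hwe_chi2,
    inflation_factor,
    ld_r2,
    qc_genotypes,
    run_gwas,
    snp_variance_explained,
)


def _panel(geno, chrom=None, pos=None):
    geno = np.asarray(geno, dtype=float)
    m = geno.shape[1]
    info = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "counted_allele": "B",
        }
    )
    return GenotypeMatrix(geno, np.arange(1, geno.shape[0] + 1), info)


class TestHwe:
    @pytest.mark.parametrize(
        "counts, expected",
        [((25, 50, 25), 0.0), ((30, 40, 30), 4.0), ((50, 0, 50), 100.0)],
    )
    def test_hand_computed_chi2(self, counts, expected):
        assert hwe_chi2(*counts) == pytest.approx(expected)

    def test_monomorphic_is_zero_by_convention(self):
        assert hwe_chi2(100, 0, 0) == 0.0

    def test_empty_counts_raise(self):
        with pytest.raises(InputError):
            hwe_chi2(0, 0, 0)


class TestQc:
    def test_rules_applied_per_snp(self):
        rng = np.random.default_rng(0)
        n = 700  # the half/half HWE column then has chi2 = 700 > 600
        good = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        rare = rng.binomial(2, 0.005, size=(n, 1)).astype(float)   # MAF < 0.01
        hwe_bad = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2.0)])[:, None]
        low_call = good.copy()
        low_call[: n // 10, 0] = np.nan                            # call rate 0.9
        sexchrom = good.copy()
        geno = np.hstack([good, rare, hwe_bad, low_call, sexchrom])
        panel = _panel(geno, chrom=[1, 1, 1, 1, "X"])
        out, report = qc_genotypes(panel)
        assert list(out.snp_info["snp"]) == ["s0"]
        assert report["dropped_maf"] == 1
        assert report["dropped_hwe"] == 1
        assert report["dropped_call_rate"] == 1
        assert report["dropped_nonautosomal_or_unmapped"] == 1

    def test_hwe_rule_uses_exact_statistic(self):
        # genotype counts (300, 0, 300): chi2 = 600 exactly -> not > 600, kept
        col = np.concatenate([np.zeros(300), np.full(300, 2.0)])[:, None]
        panel = _panel(col)
        assert hwe_chi2(300, 0, 300) == pytest.approx(600.0)
        out, _ = qc_genotypes(panel, maf_min=0.0)
        assert out.n_snps == 1
        # a stricter threshold must drop it (2-SNP panel so output is non-empty)
        rng = np.random.default_rng(1)
        panel2 = _panel(
            np.hstack([col, rng.binomial(2, 0.4, size=(600, 1)).astype(float)])
        )
        _, rep = qc_genotypes(panel2, maf_min=0.0, hwe_chi2_max=599.0)
        assert rep["dropped_hwe"] == 1

    def test_empty_panel_raises(self):
        panel = _panel(np.zeros((50, 2)) + 1.0, chrom=["X", "Y"])
        with pytest.raises(InputError):
            qc_genotypes(panel)


class TestGrm:
    def test_matches_dense_textbook_formula(self):
        rng = np.random.default_rng(5)
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, 10), size=(5, 10)).astype(float)
        panel = _panel(geno)
        grm = compute_grm(panel)
        p = geno.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        M = geno[:, keep] - 2 * p[keep]
        expected = M @ M.T / (2 * np.sum(p[keep] * (1 - p[keep])))
        assert np.allclose(grm.matrix, expected)

    def test_identical_animals_share_diagonal_value(self):
        geno = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=float)
        grm = compute_grm(_panel(geno))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])

    def test_unrelated_hwe_sample_has_unit_diagonal(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.5, 5000)
        geno = rng.binomial(2, p, size=(500, 5000)).astype(float)
        grm = compute_grm(_panel(geno))
        assert np.abs(np.mean(np.diag(grm.matrix)) - 1.0) < 0.05

    def test_monomorphic_snp_excluded_with_warning(self):
        geno = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(_panel(geno))
        assert grm.n_snps == 1


class TestSnpVariance:
    @pytest.mark.parametrize(
        "p, beta, s2a, expected_share",
        [(0.49, 0.019, 0.012, 0.015), (0.48, 0.020, 0.014, 0.014)],
    )
    def test_genetic_share_reproduces_printed_values(self, p, beta, s2a, expected_share):
        _, share, _ = snp_variance_explained(p, beta, s2a, sigma2_P=1.0)
        assert round(share, 3) == expected_share

    def test_boundary_and_maximum(self):
        assert snp_variance_explained(0.0, 0.3, 1.0, 1.0)[0] == 0.0
        mid = snp_variance_explained(0.5, 0.3, 1.0, 1.0)[0]
        off = snp_variance_explained(0.3, 0.3, 1.0, 1.0)[0]
        assert mid > off

    def test_invalid_frequency_raises(self):
        with pytest.raises(ConfigurationError):
            snp_variance_explained(1.2, 0.1, 1.0, 1.0)


class TestLd:
    def test_identical_and_flipped_columns(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        g2 = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        assert ld_r2(g1, g2) == pytest.approx(0.5625)

    def test_monomorphic_is_nan(self):
        assert np.isnan(ld_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2.0])))


class TestAssociation:
    def test_beta_equals_ols_with_identity_grm(self):
        """Identity GRM collapses the mixed model to per-SNP OLS."""
        rng = np.random.default_rng(2)
        n, m = 300, 25
        geno = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = rng.normal(size=n) + 0.3 * geno[:, 3]
        panel = _panel(geno)
        grm = GrmMatrix(np.eye(n), panel.animals, m)
        res = run_gwas(pd.DataFrame({"animal": panel.animals, "debv": y}), panel, grm)
        for j in (0, 3, 11):
            slope = np.polyfit(geno[:, j], y, 1)[0]
            assert res.loc[j, "beta"] == pytest.approx(slope, abs=1e-6)

    def test_orthogonal_snp_not_significant(self):
        rng = np.random.default_rng(3)
        n = 400
        geno = rng.binomial(2, 0.3, size=(n, 150)).astype(float)
        y = rng.normal(size=n)
        panel = _panel(geno)
        grm = compute_grm(panel)
        res = run_gwas(pd.DataFrame({"animal": panel.animals, "debv": y}), panel, grm)
        z = (res["beta"] / res["se"]).abs()
        assert (z < 2).mean() >= 0.90
        assert (res["snp_class"] == "significant").sum() == 0

    def test_per_snp_reml_agrees_with_fixed_ratio_mode(self):
        rng = np.random.default_rng(7)
        n, m = 500, 20
        geno = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        panel = _panel(geno)
        grm = compute_grm(panel)
        L = np.linalg.cholesky(grm.matrix + 1e-4 * np.eye(n))
        y = 0.4 * (L @ rng.standard_normal(n)) + rng.normal(0, 0.6, n)
        tab = pd.DataFrame({"animal": panel.animals, "debv": y})
        fast = run_gwas(tab, panel, grm)
        exact = run_gwas(tab, panel, grm, per_snp_reml=True)
        assert np.allclose(fast["beta"], exact["beta"], atol=0.01)
        ratio = fast["se"] / exact["se"]
        assert np.all((ratio > 0.9) & (ratio < 1.1))

    def test_too_few_common_animals_raises(self):
        panel = _panel(np.zeros((5, 3)) + 1.0)
        grm = GrmMatrix(np.eye(5), panel.animals, 3)
        y = pd.DataFrame({"animal": [99], "debv": [0.1]})
        with pytest.raises(InputError):
            run_gwas(y, panel, grm)


class TestRegions:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["snp", "chrom", "pos", "p_value", "snp_class"]
        )

    def test_singleton_region(self):
        res = self._results([("a", 1, 100, 1e-8, "significant")])
        panel = _panel(np.array([[0.0], [1.0], [2.0]]))
        panel.snp_info["snp"] = ["a"]
        regions = define_vqtl_regions(res, panel)
        assert len(regions) == 1 and regions[0].snps == ["a"]

    def test_linked_suggestives_join_unlinked_stay_out(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, 60).astype(float)
        other = rng.binomial(2, 0.5, 60).astype(float)
        geno = np.column_stack([base, base, base, other])
        panel = _panel(geno, pos=[100, 200, 300, 4000])
        res = self._results(
            [
                ("s0", 1, 100, 1e-8, "significant"),
                ("s1", 1, 200, 1e-5, "suggestive"),
                ("s2", 1, 300, 5e-5, "suggestive"),
                ("s3", 1, 4000, 2e-5, "suggestive"),
            ]
        )
        regions = define_vqtl_regions(res, panel, r2_min=0.2)
        assert len(regions) == 1
        assert regions[0].snps == ["s0", "s1", "s2"]
        assert regions[0].index_snp == "s0"

    def test_region_calling_is_deterministic(self):
        rng = np.random.default_rng(9)
        geno = rng.binomial(2, 0.4, size=(80, 6)).astype(float)
        panel = _panel(geno)
        res = self._results(
            [
                ("s0", 1, 1000, 1e-9, "significant"),
                ("s1", 1, 2000, 1e-7, "significant"),
                ("s2", 1, 2500, 3e-5, "suggestive"),
                ("s3", 1, 9000, 2e-5, "suggestive"),
                ("s4", 2, 1000, 5e-5, "suggestive"),
                ("s5", 1, 500, 0.5, "null"),
            ]
        )
        r1 = define_vqtl_regions(res, panel, r2_min=0.1)
        r2 = define_vqtl_regions(res, panel, r2_min=0.1)
        assert [(r.chrom, r.start, r.end, tuple(r.snps)) for r in r1] == [
            (r.chrom, r.start, r.end, tuple(r.snps)) for r in r2
        ]


class TestIngest:
    def test_plink_ped_map_roundtrip(self, tmp_path):
        from littervar.gwas import read_plink_ped

        (tmp_path / "toy.map").write_text(
            "1 s1 0 1000\n1 s2 0 2000\n2 s3 0 500\n"
        )
        (tmp_path / "toy.ped").write_text(
            "F1 A1 0 0 2 -9 A A A G G G\n"
            "F1 A2 0 0 2 -9 A G G G 0 0\n"
            "F2 A3 0 0 2 -9 G G A G G G\n"
        )
        g = read_plink_ped(tmp_path / "toy.ped", tmp_path / "toy.map")
        assert list(g.animals) == ["A1", "A2", "A3"]
        # counted allele is the first seen per SNP: A, A, G
        assert g.genotypes[0, 0] == 2 and g.genotypes[1, 0] == 1 and g.genotypes[2, 0] == 0
        assert np.isnan(g.genotypes[1, 2])
        assert list(g.snp_info["chrom"]) == [1, 1, 2]

    def test_vcf_ingest_counts_alt_allele(self, tmp_path):
        from littervar.gwas import read_vcf

        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tA3\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1\n"
        )
        g = read_vcf(vcf)
        assert g.n_snps == 2 and g.n_animals == 3
        assert list(g.genotypes[:, 0]) == [0.0, 1.0, 2.0]
        assert np.isnan(g.genotypes[0, 1]) and g.genotypes[2, 1] == 1.0

    def test_dosage_tsv_roundtrip(self, tmp_path):
        from littervar.gwas import read_dosage_tsv
        from littervar.simdata import SimConfig, simulate_pedigree, simulate_genotypes, write_genotypes

        cfg = SimConfig(n_sires=2, n_dams_per_sire=2, n_generations=1,
                        n_snps=10, n_chromosomes=2, seed=3)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        write_genotypes(geno, tmp_path / "g.tsv", tmp_path / "m.tsv")
        back = read_dosage_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
        assert np.array_equal(back.genotypes, geno.genotypes)
        assert list(back.snp_info["snp"]) == list(geno.snp_info["snp"])


class TestInflation:
    def test_all_half_pvalues_give_lambda_one(self):
        assert inflation_factor(np.full(500, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_close_to_one(self):
        rng = np.random.default_rng(12)
        lam = inflation_factor(rng.uniform(size=10_000))
        assert 0.95 < lam < 1.05

    def test_doubled_chi2_doubles_lambda(self):
        rng = np.random.default_rng(13)
        chi = rng.chisquare(1, size=20_000)
        p = stats.chi2.sf(2 * chi, df=1)
        assert inflation_factor(p) == pytest.approx(2.0, rel=0.05)

    def test_out_of_range_pvalues_raise(self):
        with pytest.raises(InputError):
            inflation_factor(np.concatenate([np.full(200, 0.5), [0.0]]))

    def test_too_few_pvalues_raise(self):
        with pytest.raises(InputError):
            inflation_factor(np.full(50, 0.5))
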
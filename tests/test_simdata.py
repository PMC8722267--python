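"""Generator contracts: pedigree structure, gene dropping, phenotype model."""

import numpy as np
import pytest
from scipy import stats

from littervar.errors import ConfigurationError
from littervar.simdata import (
    SimConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def _cfg(**kw):
    base = dict(
        n_sires=4,
        n_dams_per_sire=5,
        n_generations=1,
        litters_per_sow_range=(2, 5),
        n_snps=40,
        n_chromosomes=2,
        seed=123,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePedigree:
    def test_counts_forced_by_config(self):
        ped = simulate_pedigree(_cfg(n_sires=2, n_dams_per_sire=2))
        assert ped.n == 8                       # 4 founders + 2 x 2 offspring
        assert int(ped.is_founder().sum()) == 4

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(_cfg(n_generations=3))
        idx = np.arange(ped.n)
        assert np.all(ped.sire[ped.sire >= 0] < idx[ped.sire >= 0])
        assert np.all(ped.dam[ped.dam >= 0] < idx[ped.dam >= 0])

    def test_depth_recursion_matches_generations(self):
        ped = simulate_pedigree(_cfg(n_sires=3, n_dams_per_sire=3, n_generations=5))
        depth = ped.depth
        last = ped.meta["generation"].to_numpy() == 5
        assert depth.max() == 5
        assert np.mean(depth[last]) == pytest.approx(5.0)

    def test_zero_sires_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            _cfg(n_sires=0)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(r_a_av=1.5)

    def test_single_litter_range_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(litters_per_sow_range=(1, 5))


class TestSimulateGenotypes:
    def test_mendelian_forcing(self):
        cfg = _cfg(maf_range=(0.4, 0.5), seed=7)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        g = geno.genotypes
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0:
                both_zero = (g[s] == 0) & (g[d] == 0)
                assert np.all(g[i][both_zero] == 0)
                both_two = (g[s] == 2) & (g[d] == 2)
                assert np.all(g[i][both_two] == 2)

    def test_founder_maf_within_binomial_error(self):
        cfg = SimConfig(
            n_sires=250,
            n_dams_per_sire=250,
            n_generations=1,
            n_snps=1,
            n_chromosomes=1,
            maf_range=(0.3, 0.3),
            seed=99,
        )
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        founders = ped.is_founder()
        p_hat = geno.genotypes[founders, 0].mean() / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * founders.sum()))
        assert abs(p_hat - 0.3) < 3 * se

    def test_adjacent_ld_exceeds_distant_ld(self):
        cfg = SimConfig(
            n_sires=4,
            n_dams_per_sire=6,
            n_generations=3,
            n_snps=60,
            n_chromosomes=1,
            recomb_rate=0.02,
            maf_range=(0.2, 0.5),
            seed=17,
        )
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        g = geno.genotypes[~ped.is_founder()]

        def mean_r2(pairs):
            vals = []
            for i, j in pairs:
                gi, gj = g[:, i], g[:, j]
                if np.std(gi) > 0 and np.std(gj) > 0:
                    vals.append(np.corrcoef(gi, gj)[0, 1] ** 2)
            return np.mean(vals)

        adjacent = [(i, i + 1) for i in range(59)]
        distant = [(i, i + 30) for i in range(30)]
        assert mean_r2(adjacent) > mean_r2(distant)

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(maf_range=(0.0, 0.6))


class TestSimulatePhenotypes:
    def test_homoscedastic_when_variance_parts_zero(self):
        cfg = SimConfig(
            n_sires=20,
            n_dams_per_sire=25,
            n_generations=1,
            litters_per_sow_range=(6, 10),
            var_av=0.0,
            var_pev=0.0,
            r_a_av=0.0,
            r_pe_pev=0.0,
            n_snps=0,
            seed=5,
        )
        ped = simulate_pedigree(cfg)
        records, truth = simulate_phenotypes(ped, cfg)
        assert np.allclose(truth.record_sd, truth.record_sd[0])
        # Levene-type check: within-sow deviations have equal spread across
        # arbitrary sow buckets
        dev = records["tnb"] - records.groupby("sow")["tnb"].transform("mean")
        buckets = [
            dev[records["sow"].to_numpy() % 5 == k].to_numpy() for k in range(5)
        ]
        assert stats.levene(*buckets).pvalue > 0.01

    def test_phenotypic_variance_matches_component_sum(self):
        """Net of fixed effects, var(y) ~ sigma2_a + sigma2_pe + exp(eta) = 9.86."""
        cfg = SimConfig(
            n_sires=40,
            n_dams_per_sire=50,
            n_generations=1,
            litters_per_sow_range=(5, 5),
            var_av=0.0,
            var_pev=0.0,
            r_a_av=0.0,
            r_pe_pev=0.0,
            n_snps=0,
            n_hys=1,
            hys_sd=0.0,
            parity_effects={p: 0.0 for p in range(1, 11)},
            seed=42,
        )
        ped = simulate_pedigree(cfg)
        records, _ = simulate_phenotypes(ped, cfg)
        assert records["tnb"].var() == pytest.approx(9.86, rel=0.05)

    def test_genetic_correlation_matches_config_at_large_n(self):
        cfg = SimConfig(
            n_sires=100,
            n_dams_per_sire=50,
            n_generations=1,
            litters_per_sow_range=(2, 2),
            n_snps=0,
            seed=8,
        )
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, cfg)
        r = np.corrcoef(truth.animals["u"], truth.animals["v"])[0, 1]
        assert r == pytest.approx(0.43, abs=0.03)

    def test_founder_breeding_values_center_on_zero(self):
        cfg = SimConfig(
            n_sires=300, n_dams_per_sire=300, n_generations=1, n_snps=0, seed=3
        )
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, cfg)
        founders = ped.is_founder()
        u = truth.animals.loc[founders, "u"]
        assert abs(u.mean()) < 3 * np.sqrt(1.33 / founders.sum())

    def test_planted_vqtl_shifts_variance_effect(self):
        cfg = _cfg(
            n_sires=30,
            n_dams_per_sire=30,
            causal_snp={"index": 5, "beta_v": 0.3, "beta_u": 0.0},
            seed=44,
        )
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, cfg, geno)
        dose = geno.genotypes[:, 5]
        v = truth.animals["v"].to_numpy()
        slope = np.polyfit(dose, v, 1)[0]
        assert slope == pytest.approx(0.3, abs=0.1)

    def test_integer_mode_rounds_to_support(self):
        cfg = _cfg(integer_phenotype=True)
        ped = simulate_pedigree(cfg)
        records, _ = simulate_phenotypes(ped, cfg)
        assert (records["tnb"] == records["tnb"].round()).all()
        assert (records["tnb"] >= 0).all()


def test_seeded_runs_are_identical():
    cfg = _cfg(seed=2024)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert np.array_equal(a[0].sire, b[0].sire)
    assert np.array_equal(a[1].genotypes, b[1].genotypes)
    assert a[2].equals(b[2])
    assert a[3].animals.equals(b[3].animals)
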
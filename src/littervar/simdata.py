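"""Synthetic pedigree, genotype and litter-size data generator.

The generator emulates a pig nucleus population with repeated litter-size
records (TNB, total number born) per sow under the exponential model for
micro-environmental sensitivity:

    y = mu + fixed effects + u + pe + exp(0.5 (eta + v + pe_v)) eps

where the per-animal genetic pair (u, v) follows the pedigree with a 2x2
additive covariance (variances ``var_a``, ``var_av`` and correlation
``r_a_av``) and (pe, pe_v) is a sow-level permanent-environment pair.
Defaults reproduce the variance components estimated in the Large White
litter-size study this package models (mean TNB 13.76, additive variance
1.33, permanent-environment variance 0.86, residual variance 7.67, additive
variance 0.037 for the log residual variance, genetic correlation 0.43 and
permanent-environment correlation -0.87), at population sizes scaled to a
desk machine.

Mating design: each generation has ``n_sires`` boars and ``n_dams_per_sire``
sows shared across boars (a sow farrows to several boars over parities, as
in commercial pig herds); every sire x dam cross contributes one offspring,
and the next generation's parents are drawn from these offspring.  A SNP
panel is dropped through the pedigree gamete by gamete with adjacent-locus
recombination, optionally with one causal variant affecting the variance
(and/or mean) genetic effect - the planted vQTL for power studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gwas import GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["SimConfig", "TruthSet", "simulate_pedigree", "simulate_genotypes",
           "simulate_phenotypes", "simulate_dataset", "default_parity_effects"]


def default_parity_effects() -> dict[int, float]:
    """Concave 'parity curve': litter size rises to mid parities, then falls."""
    return {p: round(1.4 * math.exp(-((p - 4.5) ** 2) / 10.0) - 0.5, 3) for p in range(1, 11)}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_sires: int = 25
    n_dams_per_sire: int = 20
    n_generations: int = 1
    litters_per_sow_range: tuple[int, int] = (2, 10)
    mu: float = 13.76
    eta: float = math.log(7.67)
    var_a: float = 1.33
    var_av: float = 0.037
    r_a_av: float = 0.43
    var_pe: float = 0.86
    var_pev: float = 0.15
    r_pe_pev: float = -0.87
    parity_effects: dict[int, float] = field(default_factory=default_parity_effects)
    n_hys: int = 20
    hys_sd: float = 0.7
    n_snps: int = 2000
    n_chromosomes: int = 5
    recomb_rate: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snp: dict | None = None     # {"index": int, "beta_v": float, "beta_u": float}
    integer_phenotype: bool = False
    seed: int = 1234

    def __post_init__(self):
        if self.n_sires < 1 or self.n_dams_per_sire < 1 or self.n_generations < 1:
            raise ConfigurationError("population counts must be >= 1")
        for name in ("var_a", "var_av", "var_pe", "var_pev"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("r_a_av", "r_pe_pev"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [-1, 1]")
        lo, hi = self.litters_per_sow_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(
                "litters_per_sow_range minimum must be >= 2 (a within-sow "
                "variance needs at least two records)"
            )
        if (
            self.n_generations > 1
            and self.n_sires + self.n_dams_per_sire > self.n_sires * self.n_dams_per_sire
        ):
            raise ConfigurationError("not enough offspring per generation to replace parents")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie inside (0, 0.5]")

    def additive_cov(self) -> np.ndarray:
        c = self.r_a_av * math.sqrt(self.var_a * self.var_av)
        return np.array([[self.var_a, c], [c, self.var_av]])

    def pe_cov(self) -> np.ndarray:
        c = self.r_pe_pev * math.sqrt(self.var_pe * self.var_pev)
        return np.array([[self.var_pe, c], [c, self.var_pev]])


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    animals: pd.DataFrame          # animal, u, v, pe, pe_v (pe NaN for non-sows)
    record_sd: np.ndarray          # true residual SD per record
    causal_snp: dict | None
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        return self.animals.copy()


def _rng_for(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Factorial-mating pedigree; founders coded with unknown parents.

    ``ped.meta`` records generation, sex and role ("sire"/"dam"/"sow") per
    animal.  Offspring promoted to the next generation's boars are male; all
    other offspring are sows (candidate phenotype carriers).
    """
    rng = _rng_for(config, 0)
    ns, nd = config.n_sires, config.n_dams_per_sire
    ids, sire, dam, gen, sex = [], [], [], [], []

    def add(s, d, g, x):
        ids.append(len(ids) + 1)
        sire.append(s)
        dam.append(d)
        gen.append(g)
        sex.append(x)
        return len(ids) - 1

    sires = [add(-1, -1, 0, "M") for _ in range(ns)]
    dams = [add(-1, -1, 0, "F") for _ in range(nd)]
    for g in range(1, config.n_generations + 1):
        offspring = [add(s, d, g, "F") for s in sires for d in dams]
        if g < config.n_generations:
            picks = rng.permutation(len(offspring))
            sires = [offspring[i] for i in picks[:ns]]
            dams = [offspring[i] for i in picks[ns : ns + nd]]
            for i in picks[:ns]:
                sex[offspring[i]] = "M"
    meta = pd.DataFrame({"generation": gen, "sex": sex})
    meta["role"] = np.where(
        meta["sex"] == "M", "sire", np.where(meta["generation"] == 0, "dam", "sow")
    )
    return Pedigree(np.asarray(ids), np.asarray(sire), np.asarray(dam), meta=meta)


def _chromosome_of(config: SimConfig) -> np.ndarray:
    return np.minimum(
        np.arange(config.n_snps) * config.n_chromosomes // config.n_snps,
        config.n_chromosomes - 1,
    )


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene dropping through the pedigree with adjacent-locus recombination.

    Founder haplotypes are drawn from per-SNP allele frequencies sampled in
    ``maf_range``; each meiosis copies one parental haplotype per locus,
    switching between the two with probability ``recomb_rate`` between
    adjacent loci (probability 1/2 across chromosome boundaries).
    """
    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    rng = _rng_for(config, 1)
    n, m = ped.n, config.n_snps
    chrom = _chromosome_of(config)
    new_chrom = np.empty(m, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    hap = np.zeros((n, 2, m), dtype=np.int8)

    def gamete(parent_idx):
        switch = rng.random(m) < config.recomb_rate
        switch[new_chrom] = rng.random(int(new_chrom.sum())) < 0.5
        which = np.cumsum(switch) % 2
        return hap[parent_idx, which, np.arange(m)]

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        hap[i, 0] = (
            gamete(s) if s >= 0 else (rng.random(m) < freq).astype(np.int8)
        )
        hap[i, 1] = (
            gamete(d) if d >= 0 else (rng.random(m) < freq).astype(np.int8)
        )
    geno = hap.sum(axis=1).astype(float)
    info = pd.DataFrame(
        {
            "snp": [f"SNP{j + 1:06d}" for j in range(m)],
            "chrom": chrom + 1,
            "pos": (np.arange(m) - np.searchsorted(chrom, chrom)) * 50_000 + 50_000,
            "counted_allele": "B",
        }
    )
    return GenotypeMatrix(geno, ped.ids.copy(), info)


def simulate_phenotypes(
    ped: Pedigree, config: SimConfig, genotypes: GenotypeMatrix | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Repeated litter records under the exponential variance model.

    Breeding-value pairs (u, v) are propagated through the pedigree as
    parent average plus Mendelian sampling with covariance D_i * G0 (D_i the
    inbreeding-adjusted within-family variance), so the simulated values are
    exactly consistent with the A-matrix used at fitting time.  Returns the
    record table (sow, parity, hys, fys_first, tnb) and the truth set.
    """
    rng = _rng_for(config, 2)
    g0 = config.additive_cov()
    p0 = config.pe_cov()
    n = ped.n
    d_scale = ped.mendelian_variance
    # propagate (u, v); founders have D_i = 1 so the same draw covers them
    chol_g = _safe_chol(g0)
    ms = (rng.standard_normal((n, 2)) @ chol_g.T) * np.sqrt(d_scale)[:, None]
    uv = np.zeros((n, 2))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(2)
        if s >= 0:
            pa += 0.5 * uv[s]
        if d >= 0:
            pa += 0.5 * uv[d]
        uv[i] = pa + ms[i]
    if config.causal_snp is not None:
        if genotypes is None:
            raise ConfigurationError("causal_snp configured but no genotypes supplied")
        spec = config.causal_snp
        dose = genotypes.genotypes[:, int(spec["index"])]
        uv[:, 1] += float(spec.get("beta_v", 0.0)) * dose
        uv[:, 0] += float(spec.get("beta_u", 0.0)) * dose

    is_sow = (
        ped.meta["role"].to_numpy() == "sow"
        if ped.meta is not None
        else ~ped.is_founder()
    )
    sow_idx = np.nonzero(is_sow)[0]
    pe = np.full((n, 2), np.nan)
    pe[sow_idx] = rng.standard_normal((len(sow_idx), 2)) @ _safe_chol(p0).T

    hys_effects = rng.normal(0.0, config.hys_sd, size=config.n_hys)
    parity_eff = dict(config.parity_effects)
    lo, hi = config.litters_per_sow_range
    n_litters = rng.integers(lo, hi + 1, size=len(sow_idx))

    rows = []
    sds = []
    for k, i in enumerate(sow_idx):
        sow_id = ped.ids[i]
        hys = rng.integers(0, config.n_hys, size=n_litters[k])
        sd = math.exp(0.5 * (config.eta + uv[i, 1] + pe[i, 1]))
        eps = rng.standard_normal(n_litters[k])
        for parity in range(1, n_litters[k] + 1):
            pcap = min(parity, 10)
            yv = (
                config.mu
                + parity_eff.get(pcap, 0.0)
                + hys_effects[hys[parity - 1]]
                + uv[i, 0]
                + pe[i, 0]
                + sd * eps[parity - 1]
            )
            rows.append((sow_id, parity, int(hys[parity - 1]), int(hys[0]), yv))
            sds.append(sd)
    table = pd.DataFrame(rows, columns=["sow", "parity", "hys", "fys_first", "tnb"])
    if config.integer_phenotype:
        table["tnb"] = table["tnb"].round().clip(lower=0).astype(int)
    truth_animals = pd.DataFrame(
        {
            "animal": ped.ids,
            "u": uv[:, 0],
            "v": uv[:, 1],
            "pe": pe[:, 0],
            "pe_v": pe[:, 1],
        }
    )
    truth = TruthSet(
        animals=truth_animals,
        record_sd=np.asarray(sds),
        causal_snp=config.causal_snp,
        config=config,
    )
    return table, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: pedigree + genotypes + records + truth."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config) if config.n_snps else None
    records, truth = simulate_phenotypes(ped, config, geno)
    return ped, geno, records, truth


def _safe_chol(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of zero variances / singular 2x2 matrices."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, q = np.linalg.eigh(cov)
        return q @ np.diag(np.sqrt(np.maximum(w, 0.0)))


# --------------------------------------------------------------------- #
# plain-text writers (tab-delimited, header row)
# --------------------------------------------------------------------- #
def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_genotypes(geno: GenotypeMatrix, matrix_path, map_path) -> None:
    mat = pd.DataFrame(geno.genotypes, columns=geno.snp_info["snp"])
    mat.insert(0, "animal", geno.animals)
    mat.to_csv(matrix_path, sep="\t", index=False)
    geno.snp_info.to_csv(map_path, sep="\t", index=False)


def write_truth(truth: TruthSet, path) -> None:
    truth.animals.to_csv(path, sep="\t", index=False)
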
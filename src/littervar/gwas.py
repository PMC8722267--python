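"""Single-SNP mixed-linear-model GWAS for variance QTL on deregressed EBV.

The association model regresses a deregressed variability EBV on each SNP
dosage while a genomic relationship matrix absorbs polygenic covariance:

    y* = mu + x beta + u + e,   u ~ N(0, G sigma2_a*),  e ~ N(0, I sigma2_e*)

Null variance components are estimated once by REML on the eigendecomposition
of G; each SNP is then tested by generalized least squares with the null
variance ratio held fixed (the usual approximation for dense panels; exact
per-SNP REML is available for small panels).  Downstream utilities cover
genotype QC, Hardy-Weinberg tests, LD, SNP variance explained, vQTL region
calling and the genomic inflation factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, InputError

__all__ = [
    "GenotypeMatrix",
    "GrmMatrix",
    "VqtlRegion",
    "qc_genotypes",
    "hwe_chi2",
    "compute_grm",
    "run_gwas",
    "snp_variance_explained",
    "ld_r2",
    "define_vqtl_regions",
    "inflation_factor",
    "write_mlma",
    "read_plink_ped",
    "read_dosage_tsv",
    "read_vcf",
]

_CHI2_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage codes 0/1/2 (count of the counted allele).

    Missing genotypes are ``NaN``.  ``snp_info`` has one row per SNP with
    columns ``snp``, ``chrom`` (autosomes as integers; "X"/"Y"/"0" mark
    non-autosomal or unmapped), ``pos`` (1-based bp) and ``counted_allele``.
    """

    genotypes: np.ndarray
    animals: np.ndarray
    snp_info: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.animals = np.asarray(self.animals)
        if self.genotypes.shape != (len(self.animals), len(self.snp_info)):
            raise InputError("genotype matrix shape does not match animals / snp_info")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.genotypes < 0) | (self.genotypes > 2))
        if bad:
            raise InputError("genotype codes must be 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snp_info)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.genotypes), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele, per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosages_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the SNP mean."""
        g = self.genotypes.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(g, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        idx = np.where(np.isnan(g))
        g[idx] = mean[idx[1]]
        return g

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        g, animals, info = self.genotypes, self.animals, self.snp_info
        if animal_idx is not None:
            g, animals = g[animal_idx], animals[animal_idx]
        if snp_idx is not None:
            g, info = g[:, snp_idx], info.iloc[snp_idx]
        return GenotypeMatrix(g.copy(), animals.copy(), info.reset_index(drop=True))


@dataclass
class GrmMatrix:
    """VanRaden genomic relationship matrix."""

    matrix: np.ndarray
    animals: np.ndarray
    n_snps: int


@dataclass
class VqtlRegion:
    """Cluster of significant + LD-linked suggestive SNPs on one chromosome."""

    chrom: object
    start: int
    end: int
    snps: list
    index_snp: str
    index_p: float


# --------------------------------------------------------------------- #
# QC
# --------------------------------------------------------------------- #
def hwe_chi2(n0: int, n1: int, n2: int) -> float:
    """Pearson 1-df chi-square against Hardy-Weinberg genotype proportions.

    Monomorphic SNPs return 0 by convention.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise InputError("no genotyped animals")
    p = (2 * n0 + n1) / (2.0 * n)
    q = 1.0 - p
    if p <= 0.0 or q <= 0.0:
        return 0.0
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    return float(np.sum((obs - exp) ** 2 / exp))


def _is_autosomal(chrom) -> bool:
    try:
        return int(chrom) > 0
    except (TypeError, ValueError):
        return False


def qc_genotypes(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_chi2_max: float = 600.0,
    animal_missing_max: float = 0.05,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the SNP and animal quality-control rules; returns panel + report.

    SNP filters (in order): non-autosomal or unmapped position, call rate,
    minor allele frequency, Hardy-Weinberg chi-square.  Animals are filtered
    afterwards on missing-genotype frequency.
    """
    geno = g.genotypes
    n_counts = np.vstack(
        [
            np.nansum(geno == 0, axis=0),
            np.nansum(geno == 1, axis=0),
            np.nansum(geno == 2, axis=0),
        ]
    ).T
    autosomal = np.array(
        [
            _is_autosomal(c) and np.isfinite(p) and p >= 0
            for c, p in zip(g.snp_info["chrom"], pd.to_numeric(g.snp_info["pos"], errors="coerce"))
        ]
    )
    callr = g.call_rate()
    maf = g.maf()
    hwe = np.array([hwe_chi2(*row) if row.sum() else 0.0 for row in n_counts])
    keep = autosomal.copy()
    report = {"n_snps_in": g.n_snps, "dropped_nonautosomal_or_unmapped": int((~autosomal).sum())}
    drop_call = keep & (callr < call_rate_min)
    keep &= ~drop_call
    report["dropped_call_rate"] = int(drop_call.sum())
    drop_maf = keep & (maf < maf_min)
    keep &= ~drop_maf
    report["dropped_maf"] = int(drop_maf.sum())
    drop_hwe = keep & (hwe > hwe_chi2_max)
    keep &= ~drop_hwe
    report["dropped_hwe"] = int(drop_hwe.sum())
    if not keep.any():
        raise InputError("no SNPs left after quality control")
    out = g.subset(snp_idx=np.nonzero(keep)[0])
    miss = np.mean(np.isnan(out.genotypes), axis=1)
    keep_animals = miss <= animal_missing_max
    report["dropped_animals_missingness"] = int((~keep_animals).sum())
    if not keep_animals.all():
        out = out.subset(animal_idx=np.nonzero(keep_animals)[0])
    report["n_snps_out"] = out.n_snps
    report["n_animals_out"] = out.n_animals
    return out, report


# --------------------------------------------------------------------- #
# GRM
# --------------------------------------------------------------------- #
def compute_grm(g: GenotypeMatrix, per_snp_scaling: bool = False) -> GrmMatrix:
    """VanRaden method-1 GRM: G = M M' / (2 sum p(1-p)) with M centred by 2p.

    ``per_snp_scaling=True`` standardizes each SNP instead (method 2).
    Monomorphic SNPs carry no information and are excluded with a warning.
    """
    dos = g.dosages_imputed()
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNP(s) from GRM")
    dos, p = dos[:, poly], p[poly]
    if dos.shape[1] == 0:
        raise InputError("no polymorphic SNPs for GRM")
    M = dos - 2.0 * p
    if per_snp_scaling:
        M = M / np.sqrt(2.0 * p * (1.0 - p))
        grm = (M @ M.T) / M.shape[1]
    else:
        grm = (M @ M.T) / (2.0 * np.sum(p * (1.0 - p)))
    return GrmMatrix(matrix=grm, animals=g.animals.copy(), n_snps=int(poly.sum()))


# --------------------------------------------------------------------- #
# Association
# --------------------------------------------------------------------- #
def _null_reml(y: np.ndarray, eigvals: np.ndarray, yr: np.ndarray, xr: np.ndarray):
    """REML of (sigma2_g, sigma2_e) on the rotated model; returns both."""
    n, p = xr.shape

    def neg_reml(log_delta):
        d = eigvals + np.exp(log_delta)
        xtx = (xr.T / d) @ xr
        xty = (xr.T / d) @ yr
        beta = np.linalg.solve(xtx, xty)
        r = yr - xr @ beta
        ypy = float(r @ (r / d))
        s2 = ypy / (n - p)
        _, ld_x = np.linalg.slogdet(xtx)
        return 0.5 * ((n - p) * np.log(s2) + np.log(d).sum() + ld_x + (n - p))

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    delta = float(np.exp(res.x))
    d = eigvals + delta
    xtx = (xr.T / d) @ xr
    beta = np.linalg.solve(xtx, (xr.T / d) @ yr)
    r = yr - xr @ beta
    s2g = float(r @ (r / d)) / (n - p)
    return s2g, s2g * delta, delta


def run_gwas(
    y_star: pd.DataFrame,
    g: GenotypeMatrix,
    grm: GrmMatrix,
    significant: float = 1e-6,
    suggestive: float = 1e-4,
    response: str = "debv",
    per_snp_reml: bool = False,
) -> pd.DataFrame:
    """Single-SNP mixed-model association of a deregressed EBV table.

    ``y_star`` needs columns ``animal`` and ``response``.  Returns one row per
    SNP (allele frequency, effect, SE, p-value, variance explained, class);
    the fitted null components are stored in ``result.attrs``.  By default
    the null variance ratio is held fixed across SNPs; ``per_snp_reml=True``
    re-estimates it for every SNP (small panels only).
    """
    if not {"animal", response}.issubset(y_star.columns):
        raise InputError(f"y_star needs columns 'animal' and {response!r}")
    common, gi, _ = np.intersect1d(g.animals, y_star["animal"].to_numpy(), return_indices=True)
    if len(common) < 3:
        raise InputError("fewer than 3 animals shared between phenotypes and genotypes")
    if not np.array_equal(grm.animals, g.animals):
        raise InputError("GRM animals do not match genotype animals")
    sub = g.subset(animal_idx=gi)
    K = grm.matrix[np.ix_(gi, gi)]
    y = (
        y_star.set_index("animal")[response]
        .reindex(pd.Index(common))
        .to_numpy(dtype=float)
    )

    eigvals, U = np.linalg.eigh(K)
    eigvals = np.maximum(eigvals, 0.0)
    yr = U.T @ y
    xr0 = U.T @ np.ones((len(y), 1))
    s2g, s2e, delta = _null_reml(y, eigvals, yr, xr0)

    dos = sub.dosages_imputed()
    p_all = dos.mean(axis=0) / 2.0
    Xs = U.T @ dos
    if per_snp_reml:
        beta = np.full(sub.n_snps, np.nan)
        se = np.full(sub.n_snps, np.nan)
        det = np.ones(sub.n_snps)
        for j in range(sub.n_snps):
            if not 0.0 < p_all[j] < 1.0:
                continue
            xr = np.column_stack([xr0[:, 0], Xs[:, j]])
            s2g_j, _, delta_j = _null_reml(y, eigvals, yr, xr)
            dj = eigvals + delta_j
            xtx = (xr.T / dj) @ xr
            sol = np.linalg.solve(xtx, (xr.T / dj) @ yr)
            cov_b = s2g_j * np.linalg.inv(xtx)
            beta[j] = sol[1]
            se[j] = np.sqrt(cov_b[1, 1])
        poly = np.isfinite(beta)
    else:
        d = eigvals + delta
        inv_d = 1.0 / d
        a11 = float((xr0[:, 0] ** 2 * inv_d).sum())
        b1 = float((xr0[:, 0] * yr * inv_d).sum())
        a12 = (xr0[:, 0] * inv_d) @ Xs
        a22 = inv_d @ (Xs**2)
        b2 = (yr * inv_d) @ Xs
        det = a11 * a22 - a12**2
        poly = (p_all > 0) & (p_all < 1) & (det > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (a11 * b2 - a12 * b1) / det
            var_beta = s2g * a11 / det
            se = np.sqrt(var_beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = (beta / se) ** 2
    pval = stats.chi2.sf(z2, df=1)
    beta[~poly] = np.nan
    se[~poly] = np.nan
    pval[~poly] = np.nan

    s2p = s2g + s2e
    s2snp = 2.0 * p_all * (1.0 - p_all) * beta**2
    res = pd.DataFrame(
        {
            "snp": sub.snp_info["snp"].to_numpy(),
            "chrom": sub.snp_info["chrom"].to_numpy(),
            "pos": sub.snp_info["pos"].to_numpy(),
            "counted_allele": sub.snp_info.get(
                "counted_allele", pd.Series(["A"] * sub.n_snps)
            ).to_numpy(),
            "freq": p_all,
            "beta": beta,
            "se": se,
            "p_value": pval,
            "sigma2_snp": s2snp,
            "share_genetic": s2snp / s2g,
            "share_phenotypic": s2snp / s2p,
        }
    )
    res["snp_class"] = np.select(
        [res["p_value"] < significant, res["p_value"] < suggestive],
        ["significant", "suggestive"],
        default="null",
    )
    res.loc[~poly, "snp_class"] = "null"
    res.attrs.update(
        {"sigma2_a": s2g, "sigma2_e": s2e, "sigma2_P": s2p, "n_animals": len(common)}
    )
    return res


def snp_variance_explained(p: float, beta: float, sigma2_a: float, sigma2_P: float):
    """(sigma2_snp, genetic share, phenotypic share) from 2 p q beta^2."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("allele frequency must be in [0, 1]")
    if sigma2_a <= 0 or sigma2_P <= 0:
        raise ConfigurationError("variances must be positive")
    s2 = 2.0 * p * (1.0 - p) * beta**2
    return s2, s2 / sigma2_a, s2 / sigma2_P


def ld_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared dosage correlation (composite LD for unphased genotypes)."""
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = np.isfinite(g_i) & np.isfinite(g_j)
    gi, gj = g_i[ok], g_j[ok]
    if gi.size < 2 or np.std(gi) == 0 or np.std(gj) == 0:
        return float("nan")
    return float(np.corrcoef(gi, gj)[0, 1] ** 2)


def define_vqtl_regions(
    results: pd.DataFrame, g: GenotypeMatrix, r2_min: float = 0.2
) -> list[VqtlRegion]:
    """Group significant SNPs with LD-linked suggestive SNPs into regions.

    Each significant SNP seeds a region; suggestive SNPs on the same
    chromosome join when their r^2 with the seed is at least ``r2_min``;
    regions with overlapping bp spans on one chromosome are merged.
    """
    dose = {s: g.genotypes[:, k] for k, s in enumerate(g.snp_info["snp"])}
    sig = results[results["snp_class"] == "significant"]
    sugg = results[results["snp_class"] == "suggestive"]
    raw = []
    for _, row in sig.iterrows():
        members = [(row["snp"], row["pos"], row["p_value"])]
        for _, srow in sugg[sugg["chrom"] == row["chrom"]].iterrows():
            r2 = ld_r2(dose[row["snp"]], dose[srow["snp"]])
            if np.isfinite(r2) and r2 >= r2_min:
                members.append((srow["snp"], srow["pos"], srow["p_value"]))
        pos = [m[1] for m in members]
        raw.append(
            {
                "chrom": row["chrom"],
                "start": int(min(pos)),
                "end": int(max(pos)),
                "members": members,
            }
        )
    # merge overlapping spans per chromosome
    merged: list[dict] = []
    for region in sorted(raw, key=lambda r: (str(r["chrom"]), r["start"])):
        last = merged[-1] if merged else None
        if (
            last
            and last["chrom"] == region["chrom"]
            and region["start"] <= last["end"]
        ):
            last["end"] = max(last["end"], region["end"])
            seen = {m[0] for m in last["members"]}
            last["members"] += [m for m in region["members"] if m[0] not in seen]
        else:
            merged.append(region)
    out = []
    for r in merged:
        idx = min(r["members"], key=lambda m: m[2])
        out.append(
            VqtlRegion(
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                snps=[m[0] for m in sorted(r["members"], key=lambda m: m[1])],
                index_snp=idx[0],
                index_p=float(idx[2]),
            )
        )
    return out


def inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic inflation lambda: median observed 1-df chi-square / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise InputError("need at least 100 p-values to estimate lambda")
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_obs) / _CHI2_MEDIAN)


# --------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------- #
def write_mlma(results: pd.DataFrame, path) -> None:
    """Association table in the conventional .mlma column layout."""
    out = results.rename(
        columns={
            "chrom": "Chr",
            "snp": "SNP",
            "pos": "bp",
            "counted_allele": "refA",
            "beta": "b",
            "p_value": "p",
        }
    )[["Chr", "SNP", "bp", "refA", "freq", "b", "se", "p"]]
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(matrix_path, map_path) -> GenotypeMatrix:
    """Dosage matrix TSV (rows = animals, first column 'animal') + map TSV."""
    mat = pd.read_csv(matrix_path, sep="\t")
    info = pd.read_csv(map_path, sep="\t")
    if "animal" not in mat.columns:
        raise InputError("dosage matrix needs an 'animal' column")
    animals = mat["animal"].to_numpy()
    geno = mat.drop(columns="animal").to_numpy(dtype=float)
    required = {"snp", "chrom", "pos"}
    if not required.issubset(info.columns):
        raise InputError(f"map file needs columns {sorted(required)}")
    return GenotypeMatrix(geno, animals, info)


def read_plink_ped(ped_path, map_path) -> GenotypeMatrix:
    """PLINK text .ped/.map pair; counted allele = first allele seen per SNP."""
    info = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp", "cm", "pos"]
    )
    rows, animals = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 + 2 * len(info):
                raise InputError("truncated .ped line")
            animals.append(parts[1])
            rows.append(parts[6:])
    counted = [None] * len(info)
    geno = np.full((len(animals), len(info)), np.nan)
    for i, row in enumerate(rows):
        for j in range(len(info)):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            if counted[j] is None:
                counted[j] = a1
            geno[i, j] = (a1 == counted[j]) + (a2 == counted[j])
    info = info[["snp", "chrom", "pos"]].copy()
    info["counted_allele"] = [c if c is not None else "A" for c in counted]
    return GenotypeMatrix(geno, np.asarray(animals), info)


def read_vcf(path) -> GenotypeMatrix:
    """Biallelic sites from a VCF (GT field); dosage counts the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = np.asarray(vcf.samples)
    geno, records = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dose = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        geno.append(dose)
        records.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.ALT[0]))
    if not records:
        raise InputError("no biallelic records in VCF")
    info = pd.DataFrame(records, columns=["snp", "chrom", "pos", "counted_allele"])
    return GenotypeMatrix(np.asarray(geno).T, animals, info)
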
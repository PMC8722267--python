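"""End-to-end orchestration of the two variability tracks plus GWAS.

Stages (each reads and writes plain-text artifacts in the run directory, so
any stage can be re-run in isolation):

    simulate -> prep -> lnvar -> dhglm -> evaluate -> gwas -> report

``simulate`` generates pedigree/genotypes/records; ``prep`` applies the
litter-record edits; ``lnvar`` runs the two-step log-variance track;
``dhglm`` the bivariate model; ``evaluate`` compares the two EBV sets
(theoretical accuracy, correlation, deregression, paternal half-sib
cross-validation); ``gwas`` QCs the panel, builds the GRM and associates
each SNP with both deregressed EBV sets; ``report`` aggregates a summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal_model import ModelSpec, Pedigree, fit_mixed_model, heritability
from .dhglm import DhglmOptions, gcv_sde, run_dhglm
from .ebv_eval import (
    compare_methods,
    deregress_ebv,
    run_cross_validation,
    theoretical_accuracy,
)
from .errors import ConfigurationError, InputError
from .gwas import (
    compute_grm,
    define_vqtl_regions,
    inflation_factor,
    qc_genotypes,
    read_dosage_tsv,
    run_gwas,
    write_mlma,
)
from .phenoprep import apply_edit_rules, run_lnvar_track
from .simdata import (
    SimConfig,
    simulate_dataset,
    write_genotypes,
    write_pedigree,
    write_phenotypes,
    write_truth,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "prep", "lnvar", "dhglm", "evaluate", "gwas", "report")


@dataclass
class PipelineConfig:
    """Run configuration; ``simulate`` may be None when real files are given."""

    outdir: str = "runs/demo"
    seed: int = 1234
    stages: tuple = ALL_STAGES
    simulate: SimConfig | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    genotype_matrix_path: str | None = None
    genotype_map_path: str | None = None
    significant: float = 1e-6
    suggestive: float = 1e-4
    r2_min: float = 0.2
    qc: dict = field(
        default_factory=lambda: {
            "call_rate_min": 0.95,
            "maf_min": 0.01,
            "hwe_chi2_max": 600.0,
            "animal_missing_max": 0.05,
        }
    )
    dereg_c: float = 0.5
    cv_folds: int = 3
    cv_min_half_sisters: int = 3
    dhglm: dict = field(default_factory=dict)
    reml: dict = field(default_factory=dict)
    sigma2_av_floor: float = 0.005

    def __post_init__(self):
        for name in ("significant", "suggestive", "r2_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        if self.simulate is None and "simulate" in self.stages:
            self.simulate = SimConfig(seed=self.seed)
        if self.simulate is None:
            for p in (self.pedigree_path, self.phenotype_path):
                if p is None or not Path(p).exists():
                    raise ConfigurationError(
                        "simulate stage disabled but input paths missing"
                    )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("simulate", None)
        if isinstance(sim, dict):
            for key in ("litters_per_sow_range", "maf_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    return str(x)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    rundir = Path(config.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    timings = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        log.info("stage %s ...", stage)
        _STAGE_FUNCS[stage](config, rundir)
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", stage, timings[stage])
    manifest["timings"] = timings
    _dump(manifest, rundir / "manifest.json")
    return rundir


# ------------------------------------------------------------------ #
# stages
# ------------------------------------------------------------------ #
def _stage_simulate(config: PipelineConfig, rundir: Path) -> None:
    sim = config.simulate
    ped, geno, records, truth = simulate_dataset(sim)
    write_pedigree(ped, rundir / "pedigree.tsv")
    write_phenotypes(records, rundir / "records_raw.tsv")
    if geno is not None:
        write_genotypes(geno, rundir / "genotypes.tsv", rundir / "snp_map.tsv")
    write_truth(truth, rundir / "truth.tsv")


def _load_pedigree(config: PipelineConfig, rundir: Path) -> Pedigree:
    path = (
        rundir / "pedigree.tsv"
        if (rundir / "pedigree.tsv").exists()
        else config.pedigree_path
    )
    if path is None or not Path(path).exists():
        raise InputError("pedigree not found; run the simulate stage or set pedigree_path")
    return Pedigree.from_frame(pd.read_csv(path, sep="\t"))


def _load_records(config: PipelineConfig, rundir: Path, edited=True) -> pd.DataFrame:
    if edited and (rundir / "records_edited.tsv").exists():
        return pd.read_csv(rundir / "records_edited.tsv", sep="\t")
    path = (
        rundir / "records_raw.tsv"
        if (rundir / "records_raw.tsv").exists()
        else config.phenotype_path
    )
    if path is None or not Path(path).exists():
        raise InputError("records not found; run simulate/prep or set phenotype_path")
    return pd.read_csv(path, sep="\t")


def _stage_prep(config: PipelineConfig, rundir: Path) -> None:
    raw = _load_records(config, rundir, edited=False)
    edited = apply_edit_rules(raw)
    edited.to_csv(rundir / "records_edited.tsv", sep="\t", index=False)
    _dump(edited.attrs["edit_log"], rundir / "edit_log.json")


def _stage_lnvar(config: PipelineConfig, rundir: Path) -> None:
    ped = _load_pedigree(config, rundir)
    records = _load_records(config, rundir)
    track = run_lnvar_track(records, ped, **config.reml)
    track.lnvar_table.to_csv(rundir / "lnvar_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "animal": track.ebv_var.index,
            "ebv_var": track.ebv_var.to_numpy(),
            "pev_var": track.pev_var.to_numpy(),
        }
    ).to_csv(rundir / "lnvar_ebv.tsv", sep="\t", index=False)
    out = {
        "tnb_model": track.mean_fit.summary(),
        "lnvar_model": track.var_fit.summary(),
        "gcv_sde": gcv_sde(track.sigma2_avar),
    }
    _dump(out, rundir / "lnvar_fit.json")
    res = pd.DataFrame(
        {"sow": records["sow"], "residual": track.mean_fit.residuals}
    )
    res.to_csv(rundir / "tnb_residuals.tsv", sep="\t", index=False)


def _stage_dhglm(config: PipelineConfig, rundir: Path) -> None:
    ped = _load_pedigree(config, rundir)
    records = _load_records(config, rundir)
    options = DhglmOptions(**config.dhglm)
    result = run_dhglm(records, ped, options, **config.reml)
    pd.DataFrame(
        {
            "animal": result.ebv_var.index,
            "ebv_mean": result.ebv_mean.to_numpy(),
            "ebv_var": result.ebv_var.to_numpy(),
            "pev_mean": result.pev_mean.to_numpy(),
            "pev_var": result.pev_var.to_numpy(),
        }
    ).to_csv(rundir / "dhglm_ebv.tsv", sep="\t", index=False)
    _dump(result.summary(), rundir / "dhglm_fit.json")


def _stage_evaluate(config: PipelineConfig, rundir: Path) -> None:
    ped = _load_pedigree(config, rundir)
    records = _load_records(config, rundir)
    lnvar_fit = json.loads((rundir / "lnvar_fit.json").read_text())
    dhglm_fit = json.loads((rundir / "dhglm_fit.json").read_text())
    lnvar_ebv = pd.read_csv(rundir / "lnvar_ebv.tsv", sep="\t").set_index("animal")
    dhglm_ebv = pd.read_csv(rundir / "dhglm_ebv.tsv", sep="\t").set_index("animal")

    s2_lnvar = lnvar_fit["lnvar_model"]["sigma2_a"]
    s2_dhglm = dhglm_fit["sigma2_av"]
    acc = pd.DataFrame(
        {
            "animal": lnvar_ebv.index,
            "accuracy_lnvar": theoretical_accuracy(
                lnvar_ebv["pev_var"], s2_lnvar
            ).to_numpy(),
            "accuracy_dhglm": theoretical_accuracy(
                dhglm_ebv["pev_var"].reindex(lnvar_ebv.index), s2_dhglm
            ).to_numpy(),
        }
    )
    acc.to_csv(rundir / "accuracy.tsv", sep="\t", index=False)

    comp = compare_methods(lnvar_ebv["ebv_var"], dhglm_ebv["ebv_var"])

    h2_lnvar = max(min(lnvar_fit["lnvar_model"]["heritability"], 0.99), 1e-3)
    h2_dhglm = max(
        min(
            s2_dhglm
            / (s2_dhglm + dhglm_fit["sigma2_pev"] + dhglm_fit["scaling_var"]),
            0.99,
        ),
        1e-3,
    )
    for name, ebv_tab, s2, h2 in (
        ("lnvar", lnvar_ebv, s2_lnvar, h2_lnvar),
        ("dhglm", dhglm_ebv, s2_dhglm, h2_dhglm),
    ):
        dereg = deregress_ebv(
            ebv_tab["ebv_var"],
            ebv_tab["pev_var"],
            ped,
            sigma2_a=s2,
            h2=h2,
            c=config.dereg_c,
        )
        dereg.to_csv(rundir / f"debv_{name}.tsv", sep="\t", index=False)

    methods = make_default_methods(config)
    cv = run_cross_validation(
        records,
        ped,
        methods,
        k=config.cv_folds,
        seed=config.seed,
        min_half_sisters=config.cv_min_half_sisters,
    )
    cv.to_frame().to_csv(rundir / "crossval_folds.tsv", sep="\t", index=False)
    _dump(
        {
            "ebv_correlation": comp,
            "crossval_averages": cv.averages,
            "crossval_t": cv.t_statistic,
            "crossval_p_one_sided": cv.p_value,
            "n_families": cv.n_families,
        },
        rundir / "evaluation.json",
    )


def make_default_methods(config: PipelineConfig) -> dict:
    """The two variability-EBV predictors used in cross-validation."""
    options = DhglmOptions(**config.dhglm)

    def lnvar_method(train: pd.DataFrame, ped: Pedigree) -> pd.Series:
        return run_lnvar_track(train, ped, **config.reml).ebv_var

    def dhglm_method(train: pd.DataFrame, ped: Pedigree) -> pd.Series:
        return run_dhglm(train, ped, options, **config.reml).ebv_var

    return {"lnvar": lnvar_method, "dhglm": dhglm_method}


def _stage_gwas(config: PipelineConfig, rundir: Path) -> None:
    matrix = (
        rundir / "genotypes.tsv"
        if (rundir / "genotypes.tsv").exists()
        else config.genotype_matrix_path
    )
    snpmap = (
        rundir / "snp_map.tsv"
        if (rundir / "snp_map.tsv").exists()
        else config.genotype_map_path
    )
    if matrix is None or not Path(matrix).exists():
        raise InputError("genotypes not found; run simulate or set genotype paths")
    geno = read_dosage_tsv(matrix, snpmap)
    geno, qc_report = qc_genotypes(geno, **config.qc)
    _dump(qc_report, rundir / "gwas_qc.json")
    grm = compute_grm(geno)
    summary = {}
    for name in ("lnvar", "dhglm"):
        dereg = pd.read_csv(rundir / f"debv_{name}.tsv", sep="\t")
        dereg = dereg[~dereg["excluded"]]
        res = run_gwas(
            dereg,
            geno,
            grm,
            significant=config.significant,
            suggestive=config.suggestive,
        )
        res.to_csv(rundir / f"gwas_{name}.tsv", sep="\t", index=False)
        write_mlma(res, rundir / f"gwas_{name}.mlma")
        regions = define_vqtl_regions(res, geno, r2_min=config.r2_min)
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_snps": len(r.snps),
                    "index_snp": r.index_snp,
                    "index_p": r.index_p,
                    "snps": ",".join(map(str, r.snps)),
                }
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_snps", "index_snp", "index_p", "snps"],
        ).to_csv(rundir / f"vqtl_regions_{name}.tsv", sep="\t", index=False)
        pvals = res["p_value"].dropna()
        lam = inflation_factor(pvals) if len(pvals) >= 100 else float("nan")
        summary[name] = {
            "n_snps": int(len(res)),
            "n_significant": int((res["snp_class"] == "significant").sum()),
            "n_suggestive": int((res["snp_class"] == "suggestive").sum()),
            "n_regions": len(regions),
            "lambda": lam,
            "sigma2_a_star": res.attrs["sigma2_a"],
            "sigma2_e_star": res.attrs["sigma2_e"],
        }
        # QQ / Manhattan plotting data
        qq = res.dropna(subset=["p_value"]).sort_values("p_value")
        qq_out = pd.DataFrame(
            {
                "snp": qq["snp"],
                "chrom": qq["chrom"],
                "pos": qq["pos"],
                "observed_neglog10p": -np.log10(qq["p_value"]),
                "expected_neglog10p": -np.log10(
                    (np.arange(len(qq)) + 0.5) / len(qq)
                ),
            }
        )
        qq_out.to_csv(rundir / f"gwas_{name}_qq.tsv", sep="\t", index=False)
    _dump(summary, rundir / "gwas_summary.json")


def _stage_report(config: PipelineConfig, rundir: Path) -> None:
    make_report(rundir, sigma2_av_floor=config.sigma2_av_floor)


def make_report(rundir: Path, sigma2_av_floor: float = 0.005) -> Path:
    """Aggregate stage artifacts into a human-readable summary + TSV tables."""
    rundir = Path(rundir)
    needed = {
        "prep": rundir / "records_edited.tsv",
        "lnvar": rundir / "lnvar_fit.json",
        "dhglm": rundir / "dhglm_fit.json",
    }
    missing = [stage for stage, path in needed.items() if not path.exists()]
    if missing:
        raise InputError(f"cannot build report; missing stage artifacts: {missing}")
    records = pd.read_csv(needed["prep"], sep="\t")
    lnvar_fit = json.loads(needed["lnvar"].read_text())
    dhglm_fit = json.loads(needed["dhglm"].read_text())

    hist = (
        records["tnb"].round().astype(int).value_counts().sort_index().rename("count")
    )
    hist.to_frame().rename_axis("tnb").reset_index().to_csv(
        rundir / "tnb_histogram.tsv", sep="\t", index=False
    )

    comp = pd.DataFrame(
        [
            {
                "estimate": "sigma2_a",
                "tnb": lnvar_fit["tnb_model"]["sigma2_a"],
                "lnvar": lnvar_fit["lnvar_model"]["sigma2_a"],
                "dhglm_var_part": dhglm_fit["sigma2_av"],
            },
            {
                "estimate": "sigma2_pe",
                "tnb": lnvar_fit["tnb_model"]["sigma2_pe"],
                "lnvar": None,
                "dhglm_var_part": dhglm_fit["sigma2_pev"],
            },
            {
                "estimate": "sigma2_e",
                "tnb": np.mean(lnvar_fit["tnb_model"]["sigma2_e"]),
                "lnvar": np.mean(lnvar_fit["lnvar_model"]["sigma2_e"]),
                "dhglm_var_part": dhglm_fit["scaling_var"],
            },
            {
                "estimate": "heritability",
                "tnb": lnvar_fit["tnb_model"]["heritability"],
                "lnvar": lnvar_fit["lnvar_model"]["heritability"],
                "dhglm_var_part": dhglm_fit["sigma2_av"]
                / (
                    dhglm_fit["sigma2_av"]
                    + dhglm_fit["sigma2_pev"]
                    + dhglm_fit["scaling_var"]
                ),
            },
        ]
    )
    comp.to_csv(rundir / "components_summary.tsv", sep="\t", index=False)

    lines = [
        "littervar run summary",
        "=====================",
        f"records: {len(records)}  sows: {records['sow'].nunique()}",
        f"mean TNB: {records['tnb'].mean():.2f} (sd {records['tnb'].std():.2f})",
        "",
        "variance components (TNB model): "
        f"a={lnvar_fit['tnb_model']['sigma2_a']:.3f} "
        f"pe={lnvar_fit['tnb_model']['sigma2_pe']:.3f} "
        f"e={np.mean(lnvar_fit['tnb_model']['sigma2_e']):.3f} "
        f"h2={lnvar_fit['tnb_model']['heritability']:.3f}",
        f"LnVar track: sigma2_avar={lnvar_fit['lnvar_model']['sigma2_a']:.4f} "
        f"h2={lnvar_fit['lnvar_model']['heritability']:.4f} "
        f"GCV_SDe={lnvar_fit['gcv_sde']:.4f}",
        f"DHGLM track: sigma2_av={dhglm_fit['sigma2_av']:.4f} "
        f"r(a,av)={dhglm_fit['r_a_av']:.3f} r(pe,pev)={dhglm_fit['r_pe_pev']:.3f} "
        f"GCV_SDe={dhglm_fit['gcv_sde']:.4f}",
    ]
    if dhglm_fit["sigma2_av"] < sigma2_av_floor:
        lines.append(
            f"note: no variance-genetics signal (sigma2_av < {sigma2_av_floor})"
        )
    eval_path = rundir / "evaluation.json"
    if eval_path.exists():
        ev = json.loads(eval_path.read_text())
        lines += [
            "",
            f"EBV correlation between methods: {ev['ebv_correlation']['correlation']:.3f}",
            "cross-validation mean correlations: "
            + ", ".join(f"{k}={v:.3f}" for k, v in ev["crossval_averages"].items())
            + f" (one-sided paired t-test p={ev['crossval_p_one_sided']:.3f})",
        ]
    gwas_path = rundir / "gwas_summary.json"
    if gwas_path.exists():
        gw = json.loads(gwas_path.read_text())
        lines.append("")
        for name, s in gw.items():
            lines.append(
                f"GWAS ({name}): {s['n_snps']} SNPs, "
                f"{s['n_significant']} significant, {s['n_suggestive']} suggestive, "
                f"{s['n_regions']} vQTL region(s), lambda={s['lambda']:.3f}"
            )
    else:
        lines.append("")
        lines.append("GWAS stage not run; Manhattan/QQ section skipped.")
    out = rundir / "report.txt"
    out.write_text("\n".join(lines) + "\n")
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "lnvar": _stage_lnvar,
    "dhglm": _stage_dhglm,
    "evaluate": _stage_evaluate,
    "gwas": _stage_gwas,
    "report": _stage_report,
}
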
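"""Litter-record editing and the LnVar variability phenotype.

The simple variability track works in two steps: (1) a repeatability animal
model for TNB (herd-year-season and parity fixed effects, additive and
permanent-environment sow effects) provides per-record residuals; (2) the
log of the within-sow sample variance of those residuals (LnVar) becomes a
one-record-per-sow phenotype, analysed with an additive-only animal model
whose residual variance differs between nine groups of sows defined by how
many litters each sow contributed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .animal_model import MixedModelFit, ModelSpec, Pedigree, fit_mixed_model
from .errors import InputError, InvariantError

__all__ = [
    "apply_edit_rules",
    "assign_record_groups",
    "first_farrowing_fys",
    "compute_lnvar_phenotype",
    "run_lnvar_track",
    "LnVarTrackResult",
]

log = logging.getLogger(__name__)

TNB_MIN_KEEP = 4     # records with TNB <= 3 are removed
TNB_CAP = 25         # larger litters are recoded to 25
PARITY_CAP = 10      # parities 10+ are treated as parity 10


def apply_edit_rules(raw: pd.DataFrame) -> pd.DataFrame:
    """Standard litter-size edits; idempotent.

    Drops records with TNB <= 3, recodes TNB > 25 to 25 and parity > 10 to
    10, then drops sows left with a single record.  Counts per rule are
    logged and attached as ``result.attrs['edit_log']``.
    """
    required = {"sow", "parity", "tnb"}
    if not required.issubset(raw.columns):
        raise InputError(f"record table needs columns {sorted(required)}")
    tnb = pd.to_numeric(raw["tnb"], errors="coerce")
    if tnb.isna().any():
        raise InputError("non-numeric TNB values")
    out = raw.copy()
    out["tnb"] = tnb
    n0 = len(out)
    out = out[out["tnb"] >= TNB_MIN_KEEP]
    dropped_low = n0 - len(out)
    capped_tnb = int((out["tnb"] > TNB_CAP).sum())
    out.loc[out["tnb"] > TNB_CAP, "tnb"] = TNB_CAP
    capped_parity = int((out["parity"] > PARITY_CAP).sum())
    out.loc[out["parity"] > PARITY_CAP, "parity"] = PARITY_CAP
    counts = out["sow"].value_counts()
    single = counts.index[counts < 2]
    dropped_single = int(out["sow"].isin(single).sum())
    out = out[~out["sow"].isin(single)].reset_index(drop=True)
    edit_log = {
        "records_in": n0,
        "dropped_tnb_le3": dropped_low,
        "recoded_tnb_gt25": capped_tnb,
        "recoded_parity_gt10": capped_parity,
        "dropped_single_record_sows": dropped_single,
        "records_out": len(out),
        "sows_out": int(out["sow"].nunique()),
    }
    out.attrs["edit_log"] = edit_log
    log.info("edit rules: %s", edit_log)
    return out


def assign_record_groups(table: pd.DataFrame) -> pd.Series:
    """Residual-variance group per sow: group k for k+1 litters, 9 for >= 10.

    Sows with 2..9 records fall in groups 1..8; 10 or more records map to
    group 9 (nine groups in total).
    """
    counts = table.groupby("sow").size()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise InvariantError(f"sow {bad!r} has fewer than 2 records after editing")
    groups = np.minimum(counts - 1, 9).astype(int)
    groups.name = "group"
    return groups


def first_farrowing_fys(table: pd.DataFrame, hys_col: str = "hys") -> pd.Series:
    """Farm-year-season of each sow's first farrowing (lowest parity record)."""
    idx = table.groupby("sow")["parity"].idxmin()
    out = table.loc[idx].set_index("sow")[hys_col]
    out.name = "fys_first"
    return out


def compute_lnvar_phenotype(residuals_by_sow: dict) -> pd.DataFrame:
    """LnVar phenotype: log of the within-sow sample variance of residuals.

    The sample variance uses the n-1 denominator.  Sows whose residual
    variance is exactly zero (possible only with degenerate input) are
    flagged and excluded.  Returns columns (sow, lnvar, n_records, group).
    """
    rows, excluded = [], []
    for sow, res in residuals_by_sow.items():
        res = np.asarray(res, dtype=float)
        if res.size < 2:
            raise InvariantError(f"sow {sow!r} has fewer than 2 residuals")
        if not np.all(np.isfinite(res)):
            raise InputError(f"non-finite residual for sow {sow!r}")
        var = float(np.var(res, ddof=1))
        if var <= 0.0:
            excluded.append(sow)
            continue
        rows.append((sow, float(np.log(var)), int(res.size), int(min(res.size - 1, 9))))
    if excluded:
        log.warning("excluded %d sow(s) with zero residual variance", len(excluded))
    out = pd.DataFrame(rows, columns=["sow", "lnvar", "n_records", "group"])
    out.attrs["excluded_zero_variance"] = excluded
    return out


@dataclass
class LnVarTrackResult:
    """Both steps of the LnVar analysis."""

    mean_fit: MixedModelFit       # repeatability model for TNB
    lnvar_table: pd.DataFrame     # one row per sow
    var_fit: MixedModelFit        # grouped-residual model for LnVar
    ebv_var: pd.Series = field(default=None)
    pev_var: pd.Series = field(default=None)

    @property
    def sigma2_avar(self) -> float:
        return self.var_fit.varcomp.sigma2_a


def run_lnvar_track(
    records: pd.DataFrame,
    ped: Pedigree,
    hys_col: str = "hys",
    mean_fit: MixedModelFit | None = None,
    **reml_kwargs,
) -> LnVarTrackResult:
    """Run the full two-step LnVar analysis on an edited record table.

    A pre-computed TNB repeatability fit may be passed to avoid refitting
    when both variability tracks run on the same data.
    """
    if mean_fit is None:
        spec1 = ModelSpec(
            response="tnb",
            fixed=[hys_col, "parity"],
            random=["additive", "permanent_env"],
            animal="sow",
        )
        mean_fit = fit_mixed_model(spec1, records, ped, **reml_kwargs)
    res = pd.Series(mean_fit.residuals, index=records["sow"].to_numpy())
    residuals_by_sow = {sow: vals.to_numpy() for sow, vals in res.groupby(level=0)}
    lnvar = compute_lnvar_phenotype(residuals_by_sow)
    fys = first_farrowing_fys(records, hys_col=hys_col)
    lnvar = lnvar.merge(fys, left_on="sow", right_index=True, how="left")
    spec2 = ModelSpec(
        response="lnvar",
        fixed=["fys_first"],
        random=["additive"],
        animal="sow",
        residual_groups="group",
    )
    var_fit = fit_mixed_model(spec2, lnvar, ped, **reml_kwargs)
    return LnVarTrackResult(
        mean_fit=mean_fit,
        lnvar_table=lnvar,
        var_fit=var_fit,
        ebv_var=var_fit.ebv,
        pev_var=var_fit.pev,
    )
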
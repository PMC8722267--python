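"""Pedigree animal-model interface: REML variance components and BLUP EBV.

This is the model layer used by both variability tracks: the repeatability
model for litter size (fixed herd-year-season and parity effects, additive
genetic and permanent-environment sow effects) and the sow-level model for
the log-variance phenotype (fixed first-farrowing farm-year-season, additive
effect, and a separate residual variance for each record-count group).

The numerical work lives in :mod:`littervar._mme`; this module translates
tabular data and a :class:`ModelSpec` into engine terms and wraps the result
with animal ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mme import CoreFit, RandomTerm, reml_fit
from .errors import ConfigurationError, InputError
from .pedigree import Pedigree

__all__ = [
    "Pedigree",
    "ModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "build_a_inverse",
    "build_fixed_design",
    "fit_mixed_model",
    "heritability",
]


def build_a_inverse(ped: Pedigree, inbreeding: bool = True):
    """Sparse A-inverse by Henderson's rules with Meuwissen-Luo inbreeding."""
    return ped.a_inverse(inbreeding=inbreeding)


@dataclass
class ModelSpec:
    """Declarative model description for :func:`fit_mixed_model`.

    ``random`` may contain ``"additive"`` (pedigree-structured, one term) and
    ``"permanent_env"`` (identity-structured sow effect).  ``residual_groups``
    names a column of group codes for heterogeneous residual variances; None
    means a single homogeneous residual.
    """

    response: str
    fixed: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=lambda: ["additive"])
    animal: str = "sow"
    residual_groups: str | None = None

    def __post_init__(self):
        extra = set(self.random) - {"additive", "permanent_env"}
        if extra:
            raise ConfigurationError(f"unknown random terms {sorted(extra)}")
        if self.random.count("additive") > 1:
            raise ConfigurationError("at most one additive term is supported")


@dataclass
class VarianceComponents:
    """REML estimates (and SEs) on the observed scale."""

    sigma2_a: float
    sigma2_pe: float | None
    sigma2_e: np.ndarray          # one entry per residual group
    se_a: float = np.nan
    se_pe: float | None = None
    se_e: np.ndarray | None = None
    n_records_per_group: np.ndarray | None = None

    @property
    def sigma2_e_mean(self) -> float:
        """Record-weighted mean residual variance across groups."""
        e = np.atleast_1d(np.asarray(self.sigma2_e, dtype=float))
        if self.n_records_per_group is None or e.size == 1:
            return float(e.mean())
        w = np.asarray(self.n_records_per_group, dtype=float)
        return float(np.sum(w * e) / np.sum(w))


@dataclass
class MixedModelFit:
    """Converged animal-model fit: components, solutions and diagnostics."""

    varcomp: VarianceComponents
    fixed_effects: pd.Series
    ebv: pd.Series                # indexed by pedigree animal id
    pev: pd.Series
    residuals: np.ndarray         # per record, same order as the input table
    leverage: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(repr=False, default_factory=list)
    pe: pd.Series | None = None
    pe_pev: pd.Series | None = None
    core: CoreFit | None = field(repr=False, default=None)

    def reliability(self) -> pd.Series:
        """EBV reliability r^2 = 1 - PEV / sigma2_a, clipped into [0, 1]."""
        r2 = 1.0 - self.pev / max(self.varcomp.sigma2_a, 1e-300)
        return r2.clip(lower=0.0, upper=1.0)

    def summary(self) -> dict:
        vc = self.varcomp
        return {
            "sigma2_a": vc.sigma2_a,
            "sigma2_pe": vc.sigma2_pe,
            "sigma2_e": list(np.atleast_1d(vc.sigma2_e)),
            "se_a": vc.se_a,
            "heritability": heritability(vc),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def build_fixed_design(data: pd.DataFrame, factors: list[str]):
    """Intercept + reference-coded (first level dropped) factor dummies."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for f in factors:
        if f not in data.columns:
            raise InputError(f"fixed-effect column {f!r} missing from data")
        d = pd.get_dummies(data[f].astype("category"), prefix=f, drop_first=True)
        cols.append(d.to_numpy(dtype=float))
        names.extend(d.columns)
    return np.column_stack(cols), names


def fit_mixed_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    ped: Pedigree,
    weights: np.ndarray | None = None,
    var_start: dict | None = None,
    estimate: bool = True,
    **engine_kwargs,
) -> MixedModelFit:
    """REML fit (or BLUP at fixed components) of the specified animal model.

    ``var_start`` may fix/seed components: keys ``additive``, ``permanent_env``
    and ``residual`` (scalar or per-group vector).  With ``estimate=False``
    the supplied components are used as known.
    """
    if spec.response not in data.columns:
        raise InputError(f"response column {spec.response!r} missing from data")
    y = pd.to_numeric(data[spec.response], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise InputError("non-finite values in the response")
    X, xnames = build_fixed_design(data, spec.fixed)

    var_start = dict(var_start or {})
    vy = max(float(np.var(y)), 1e-6)
    terms = []
    if "additive" in spec.random:
        codes = ped.index_of(data[spec.animal].to_numpy())
        terms.append(
            RandomTerm(
                "additive",
                codes,
                ped.n,
                kinv=ped.a_inverse(),
                logdet_k=ped.logdet_a,
                cov=float(var_start.get("additive", vy / 3)),
            )
        )
    if "permanent_env" in spec.random:
        sows, sow_codes = np.unique(data[spec.animal].to_numpy(), return_inverse=True)
        terms.append(
            RandomTerm(
                "permanent_env",
                sow_codes,
                len(sows),
                cov=float(var_start.get("permanent_env", vy / 4)),
            )
        )
    if spec.residual_groups is None:
        resid_group = None
        n_groups = 1
    else:
        grp = data[spec.residual_groups].to_numpy()
        levels, resid_group = np.unique(grp, return_inverse=True)
        n_groups = len(levels)
    resid_start = np.broadcast_to(
        np.atleast_1d(np.asarray(var_start.get("residual", vy / 2), dtype=float)),
        (n_groups,),
    )

    core = reml_fit(
        y,
        X,
        terms,
        resid_group=resid_group,
        weights=weights,
        resid_start=resid_start,
        estimate=estimate,
        **engine_kwargs,
    )

    counts = (
        np.bincount(resid_group, minlength=n_groups)
        if resid_group is not None
        else np.array([len(y)])
    )
    sigma2_a = float(core.cov["additive"][0, 0]) if "additive" in core.cov else 0.0
    vc = VarianceComponents(
        sigma2_a=sigma2_a,
        sigma2_pe=(
            float(core.cov["permanent_env"][0, 0])
            if "permanent_env" in core.cov
            else None
        ),
        sigma2_e=core.resid_var.copy(),
        se_a=float(core.cov_se.get("additive", np.full((1, 1), np.nan))[0, 0]),
        se_pe=(
            float(core.cov_se["permanent_env"][0, 0])
            if "permanent_env" in core.cov
            else None
        ),
        se_e=core.resid_se.copy(),
        n_records_per_group=counts,
    )
    ebv = (
        pd.Series(core.u["additive"][0], index=pd.Index(ped.ids, name="animal"))
        if "additive" in core.u
        else pd.Series(dtype=float)
    )
    pev = (
        pd.Series(core.pev["additive"][0], index=pd.Index(ped.ids, name="animal"))
        if "additive" in core.pev
        else pd.Series(dtype=float)
    )
    pe = pe_pev = None
    if "permanent_env" in core.u:
        sows, _ = np.unique(data[spec.animal].to_numpy(), return_inverse=True)
        pe = pd.Series(core.u["permanent_env"][0], index=pd.Index(sows, name="sow"))
        pe_pev = pd.Series(core.pev["permanent_env"][0], index=pd.Index(sows, name="sow"))
    return MixedModelFit(
        varcomp=vc,
        fixed_effects=pd.Series(core.beta, index=xnames),
        ebv=ebv,
        pev=pev,
        residuals=core.residuals,
        leverage=core.leverage,
        loglik=core.loglik,
        converged=core.converged,
        n_iter=core.n_iter,
        trace=core.trace,
        pe=pe,
        pe_pev=pe_pev,
        core=core,
    )


def heritability(vc, sigma2_pe: float | None = None, sigma2_e=None) -> float:
    """h^2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e).

    Accepts either a :class:`VarianceComponents` or plain numbers
    ``heritability(sigma2_a, sigma2_pe, sigma2_e)`` (``sigma2_pe`` may be
    None).  For grouped residuals the record-weighted mean residual variance
    is used.
    """
    if isinstance(vc, VarianceComponents):
        a, p, e = vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e_mean
    else:
        a, p, e = float(vc), sigma2_pe, float(np.mean(sigma2_e))
    if a < 0 or (p is not None and p < 0) or e < 0:
        raise ConfigurationError("variance components must be non-negative")
    total = a + (p or 0.0) + e
    if total <= 0:
        raise ConfigurationError("total variance is zero")
    return a / total
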
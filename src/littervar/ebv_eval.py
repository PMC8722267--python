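"""Comparison machinery for variability EBV: accuracy, deregression and
paternal half-sib cross-validation.

Deregression follows the two-"individual" information-splitting approach of
Garrick-style pipelines: the mixed-model equations for the parent-average
pseudo-animal and the individual,

    [ Z'Z_PA + 4 lambda    -2 lambda    ] [ g_PA ]   [ y_PA ]
    [ -2 lambda            Z'Z_i + 2 lambda ] [ g_i ] = [ y_i ],

with lambda = (1 - h^2)/h^2, are inverted symbolically: the observed
reliabilities fix the diagonal of the inverse, the two effective information
contents Z'Z_PA and Z'Z_i follow in closed form, and the deregressed proof is
the individual's own-information right-hand side divided by its information
content.  GWAS weights use w = (1 - h^2) / ((c + (1 - r^2)/r^2) h^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .pedigree import Pedigree

__all__ = [
    "theoretical_accuracy",
    "deregress_ebv",
    "compare_methods",
    "run_cross_validation",
    "CrossValReport",
]

log = logging.getLogger(__name__)


def theoretical_accuracy(pev, sigma2_add: float):
    """EBV accuracy r = sqrt(1 - PEV / sigma2_add); vectorized.

    PEV numerically above sigma2_add (REML noise) is clipped to accuracy 0
    with a warning.
    """
    if sigma2_add <= 0:
        raise ConfigurationError("additive variance must be positive")
    pev_arr = np.asarray(pev, dtype=float)
    if np.any(pev_arr < 0):
        raise ConfigurationError("PEV must be >= 0")
    ratio = pev_arr / sigma2_add
    if np.any(ratio > 1):
        warnings.warn("PEV above additive variance clipped to accuracy 0")
    out = np.sqrt(np.maximum(1.0 - ratio, 0.0))
    if isinstance(pev, pd.Series):
        return pd.Series(out, index=pev.index)
    return out if out.ndim else float(out)


def _garrick_information(r2_pa: float, r2_i: float, lam: float):
    """Effective information contents (Z'Z_PA, Z'Z_i) from reliabilities.

    The parent-average pseudo-animal carries genetic variance sigma2_a/2, so
    its prediction error variance is (0.5 - r2_PA) sigma2_a, the individual's
    (1 - r2_i) sigma2_a; both pin the diagonal of the inverse coefficient
    matrix and the information contents follow from a scalar quadratic.
    """
    a = (0.5 - r2_pa) / lam          # inverse-diagonal element for PA
    b = (1.0 - r2_i) / lam           # inverse-diagonal element for individual
    det = (1.0 + np.sqrt(1.0 + 16.0 * a * b * lam**2)) / (2.0 * a * b)
    zpz_pa = b * det - 4.0 * lam
    zpz_i = a * det - 2.0 * lam
    return zpz_pa, zpz_i


def deregress_ebv(
    ebv: pd.Series,
    pev: pd.Series,
    ped: Pedigree,
    sigma2_a: float,
    h2: float,
    c: float = 0.5,
) -> pd.DataFrame:
    """Deregressed EBV, reliabilities and GWAS weights for every animal.

    ``ebv``/``pev`` are indexed by animal id (all pedigree animals).
    ``h2`` is the trait heritability used for lambda, ``c`` the fraction of
    genetic variance not explained by markers.  Animals whose reliability
    does not exceed their parent-average reliability carry no own
    information and are flagged (``excluded=True``).
    """
    if not 0.0 < h2 < 1.0:
        raise ConfigurationError("h2 must be in (0, 1)")
    if sigma2_a <= 0:
        raise ConfigurationError("sigma2_a must be positive")
    lam = (1.0 - h2) / h2
    ebv = ebv.reindex(pd.Index(ped.ids))
    pev = pev.reindex(ebv.index)
    r2 = (1.0 - pev / sigma2_a).clip(lower=0.0, upper=1.0 - 1e-8).to_numpy()
    g = ebv.to_numpy(dtype=float)
    rows = []
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        g_pa = 0.5 * ((g[s] if s >= 0 else 0.0) + (g[d] if d >= 0 else 0.0))
        r2_pa = ((r2[s] if s >= 0 else 0.0) + (r2[d] if d >= 0 else 0.0)) / 4.0
        r2_i = r2[i]
        if r2_i <= 0.0 or r2_i <= r2_pa:
            rows.append((ped.ids[i], np.nan, np.nan, np.nan, True))
            continue
        if s < 0 and d < 0:
            # no parent average exists: single-animal deregression
            debv = g[i] / r2_i
            r2_debv = r2_i
        else:
            zpz_pa, zpz_i = _garrick_information(r2_pa, r2_i, lam)
            if zpz_i <= 0.0:
                rows.append((ped.ids[i], np.nan, np.nan, np.nan, True))
                continue
            y_i = -2.0 * lam * g_pa + (zpz_i + 2.0 * lam) * g[i]
            debv = y_i / zpz_i
            r2_debv = zpz_i / (zpz_i + lam)
        w = (1.0 - h2) / ((c + (1.0 - r2_debv) / r2_debv) * h2)
        rows.append((ped.ids[i], debv, r2_debv, w, False))
    out = pd.DataFrame(rows, columns=["animal", "debv", "reliability", "weight", "excluded"])
    n_exc = int(out["excluded"].sum())
    if n_exc:
        log.info("deregression flagged %d animal(s) without own information", n_exc)
    return out


def compare_methods(ebv_a: pd.Series, ebv_b: pd.Series) -> dict:
    """Pearson correlation and top-decile overlap of two EBV rankings."""
    common = ebv_a.index.intersection(ebv_b.index)
    if len(common) < 3:
        raise InputError("fewer than 3 animals shared between the two EBV sets")
    a = ebv_a.loc[common].to_numpy(dtype=float)
    b = ebv_b.loc[common].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    n_top = max(len(common) // 10, 1)
    top_a = set(np.argsort(a)[-n_top:])
    top_b = set(np.argsort(b)[-n_top:])
    return {
        "correlation": r,
        "n_common": int(len(common)),
        "top_decile_overlap": len(top_a & top_b) / n_top,
    }


@dataclass
class CrossValReport:
    """Per-fold validation correlations and the across-fold comparison."""

    folds: list                     # dicts: masked sows + per-method correlation
    method_names: list
    averages: dict
    pooled: dict                    # per-method correlation over all masked sows
    t_statistic: float
    p_value: float                  # one-sided, second method more precise
    seed: int
    n_families: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, fold in enumerate(self.folds, start=1):
            row = {"fold": k, "n_masked": len(fold["masked"])}
            row.update(fold["correlations"])
            rows.append(row)
        return pd.DataFrame(rows)


def run_cross_validation(
    records: pd.DataFrame,
    ped: Pedigree,
    methods: dict,
    k: int = 3,
    seed: int = 0,
    min_half_sisters: int = 3,
    min_masked_warn: int = 30,
) -> CrossValReport:
    """Paternal half-sib k-fold validation of variability EBV.

    Qualifying paternal families have at least ``min_half_sisters`` recorded
    daughters; per fold one (seeded, distinct across folds) daughter per
    family has all her records masked.  Each method -- a callable
    ``(train_records, ped) -> Series of variability EBV per animal`` -- is
    re-fit on the training records, and its predicted EBV for the masked
    sows are correlated with their realized log within-sow variance of TNB
    computed from the masked records.  A paired one-sided t-test across
    folds compares the last method against the first.
    """
    if k < 2:
        raise ConfigurationError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    recorded = pd.Index(records["sow"].unique())
    pos = ped.index_of(recorded.to_numpy())
    sires = ped.sire[pos]
    fam = pd.DataFrame({"sow": recorded, "sire": sires})
    fam = fam[fam["sire"] >= 0]
    by_sire = fam.groupby("sire")["sow"].apply(list)
    qualifying = by_sire[by_sire.str.len() >= max(min_half_sisters, k)]
    if len(qualifying) == 0:
        raise InputError("no paternal families with enough recorded half-sisters")
    fold_masked: list[list] = [[] for _ in range(k)]
    for daughters in qualifying:
        picks = rng.permutation(len(daughters))[:k]
        for f, j in enumerate(picks):
            fold_masked[f].append(daughters[j])

    names = list(methods)
    folds = []
    pooled_pred: dict[str, list] = {name: [] for name in names}
    pooled_real: list = []
    for f in range(k):
        masked = fold_masked[f]
        if len(masked) < min_masked_warn:
            warnings.warn(f"fold {f + 1}: only {len(masked)} masked sows")
        train = records[~records["sow"].isin(masked)].reset_index(drop=True)
        realized = (
            records[records["sow"].isin(masked)]
            .groupby("sow")["tnb"]
            .apply(lambda v: np.var(v, ddof=1))
        )
        realized = realized[realized > 0].apply(np.log)
        corr = {}
        for name, fit_method in methods.items():
            ebv_var = fit_method(train, ped)
            pred = ebv_var.reindex(realized.index)
            corr[name] = float(np.corrcoef(pred.to_numpy(), realized.to_numpy())[0, 1])
            # center within fold so pooling compares predictions, not fold means
            pooled_pred[name].append(pred.to_numpy() - pred.to_numpy().mean())
        pooled_real.append(realized.to_numpy() - realized.to_numpy().mean())
        folds.append({"masked": masked, "correlations": corr})

    averages = {
        name: float(np.mean([f["correlations"][name] for f in folds])) for name in names
    }
    real_all = np.concatenate(pooled_real)
    pooled = {
        name: float(np.corrcoef(np.concatenate(pooled_pred[name]), real_all)[0, 1])
        for name in names
    }
    t_stat = p_val = float("nan")
    if len(names) >= 2:
        first = np.array([f["correlations"][names[0]] for f in folds])
        last = np.array([f["correlations"][names[-1]] for f in folds])
        t_stat, p_two = stats.ttest_rel(last, first)
        # one-sided: the later (more complex) method is more precise
        p_val = p_two / 2.0 if t_stat > 0 else 1.0 - p_two / 2.0
        t_stat = float(t_stat)
    return CrossValReport(
        folds=folds,
        method_names=names,
        averages=averages,
        pooled=pooled,
        t_statistic=t_stat,
        p_value=float(p_val),
        seed=seed,
        n_families=int(len(qualifying)),
    )
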
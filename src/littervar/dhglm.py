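"""Double hierarchical generalized linear model for litter-size variability.

The DHGLM couples two animal models: the mean model for TNB and a variance
model for the log residual variance of each record,

    [y; psi] = blockdiag(X, X_v)[b; b_v] + blockdiag(Z, Z_v)[a; a_v]
             + blockdiag(U, U_v)[pe; pe_v] + [e; e_v]

with e ~ N(0, W^-1 sigma2_e), e_v ~ N(0, W_v^-1 sigma2_ev), a 2x2 additive
covariance matrix (Kronecker with the pedigree A) and a 2x2 sow
permanent-environment covariance.  W = diag(exp(psi_hat))^-1 and
W_v = diag((1-h)/2) are the expected reciprocal residual variances from the
previous iterate, and the scaling variances sigma2_e, sigma2_ev are expected
to converge to 1.

The working response psi is the linearized log-link response of a gamma GLM
for the squared residuals: with d = e_hat^2/(1-h) and zeta_hat the predicted
log residual variance from the previous cycle,

    psi = zeta_hat + (d - exp(zeta_hat)) / exp(zeta_hat),

whose conditional variance 2/(1-h) is what W_v reciprocates.  At
initialization zeta_hat = log d, so psi starts as log(e_hat^2/(1-h)).

Each cycle re-fits the joint bivariate system by AI-REML (warm-started) and
refreshes psi, W and W_v until every variance component and the variance-part
EBV ranking are stable.  The variance-part EBV a_v is the second variability
phenotype (varTNB), later deregressed for the GWAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mme import RandomTerm, reml_fit
from .animal_model import MixedModelFit, ModelSpec, Pedigree, build_fixed_design, fit_mixed_model
from .errors import ConfigurationError, ConvergenceError

__all__ = ["DhglmOptions", "DhglmState", "DhglmResult", "initialize_dhglm",
           "dhglm_update", "run_dhglm", "gcv_sde"]

PSI_EPS = 1e-12


@dataclass
class DhglmOptions:
    """Iteration controls (defaults follow the package's documented choices)."""

    fixed_mean: tuple[str, ...] = ("hys", "parity")
    fixed_var: tuple[str, ...] = ("hys", "parity")
    max_cycles: int = 60
    tol_components: float = 1e-4
    tol_ebv: float = 1e-8
    damping: float = 0.7          # under-relaxation of the log-variance refresh
    reml_iters_per_cycle: int = 2
    psi_abort: float = 50.0
    start_var_av: float = 0.01
    start_var_pev: float = 0.01


@dataclass
class DhglmState:
    """One iterate of the DHGLM cycle."""

    cycle: int
    psi: np.ndarray               # working response, one per TNB record
    zeta: np.ndarray              # predicted log residual variance per record
    w_mean: np.ndarray            # mean-part weights (reciprocal resid variance)
    w_var: np.ndarray             # variance-part weights (1-h)/2
    g_cov: np.ndarray             # 2x2 additive covariance
    pe_cov: np.ndarray            # 2x2 permanent-environment covariance
    scaling: np.ndarray           # (sigma2_e, sigma2_ev)
    resid_mean: np.ndarray | None = None
    leverage_mean: np.ndarray | None = None
    ebv: np.ndarray | None = None          # (2, n_animals)
    pev: np.ndarray | None = None
    pe_sol: np.ndarray | None = None
    beta: np.ndarray | None = None
    loglik: float = np.nan
    param_cov: np.ndarray | None = None
    cov_se: dict | None = None
    resid_se: np.ndarray | None = None


@dataclass
class DhglmResult:
    """Converged DHGLM fit."""

    state: DhglmState
    ebv_mean: pd.Series
    ebv_var: pd.Series
    pev_mean: pd.Series
    pev_var: pd.Series
    psi_hat: np.ndarray           # predicted log residual variance per record
    g_cov: np.ndarray
    pe_cov: np.ndarray
    g_cov_se: np.ndarray
    pe_cov_se: np.ndarray
    scaling: np.ndarray
    scaling_se: np.ndarray
    r_a_av: float
    r_a_av_se: float
    r_pe_pev: float
    r_pe_pev_se: float
    n_cycles: int
    converged: bool
    trace: list = field(repr=False, default_factory=list)

    @property
    def sigma2_av(self) -> float:
        return float(self.g_cov[1, 1])

    def summary(self) -> dict:
        return {
            "sigma2_a": float(self.g_cov[0, 0]),
            "sigma2_av": float(self.g_cov[1, 1]),
            "sigma_a_av": float(self.g_cov[0, 1]),
            "sigma2_pe": float(self.pe_cov[0, 0]),
            "sigma2_pev": float(self.pe_cov[1, 1]),
            "r_a_av": self.r_a_av,
            "r_a_av_se": self.r_a_av_se,
            "r_pe_pev": self.r_pe_pev,
            "r_pe_pev_se": self.r_pe_pev_se,
            "scaling_mean": float(self.scaling[0]),
            "scaling_var": float(self.scaling[1]),
            "gcv_sde": gcv_sde(float(self.g_cov[1, 1])),
            "n_cycles": self.n_cycles,
            "converged": self.converged,
        }


def gcv_sde(sigma2_var_part: float) -> float:
    """Genetic coefficient of variation of the residual SD: half of
    the variance-part additive genetic standard deviation."""
    if sigma2_var_part < 0:
        raise ConfigurationError("variance-part additive variance must be >= 0")
    return 0.5 * math.sqrt(sigma2_var_part)


def initialize_dhglm(mean_fit: MixedModelFit, options: DhglmOptions | None = None) -> DhglmState:
    """Seed the iteration from a homoscedastic repeatability fit.

    psi starts as the working response linearized around the homoscedastic
    residual-variance estimate (so a record whose squared leverage-corrected
    residual equals that estimate starts at its log), the mean-part weights
    at the reciprocal of the estimated residual variance and the
    variance-part weights at (1-h)/2.
    """
    options = options or DhglmOptions()
    e = np.asarray(mean_fit.residuals, dtype=float)
    h = np.asarray(mean_fit.leverage, dtype=float)
    h = np.clip(h, 0.0, 1.0 - 1e-8)
    d = np.maximum(e**2, PSI_EPS) / (1.0 - h)
    s2e = mean_fit.varcomp.sigma2_e_mean
    # linearized log-link response around the homoscedastic estimate; equals
    # log(e^2/(1-h)) exactly when d matches the estimated residual variance
    psi = np.log(s2e) + (d - s2e) / s2e
    s2a = mean_fit.varcomp.sigma2_a
    s2pe = mean_fit.varcomp.sigma2_pe or 0.1 * s2a
    g_cov = np.array([[s2a, 0.0], [0.0, options.start_var_av]])
    pe_cov = np.array([[s2pe, 0.0], [0.0, options.start_var_pev]])
    return DhglmState(
        cycle=0,
        psi=psi,
        zeta=np.full(e.size, np.log(s2e)),
        w_mean=np.full(e.size, 1.0 / s2e),
        w_var=(1.0 - h) / 2.0,
        g_cov=g_cov,
        pe_cov=pe_cov,
        scaling=np.array([1.0, 1.0]),
        resid_mean=e,
        leverage_mean=h,
    )


def _joint_design(data: pd.DataFrame, ped: Pedigree, options: DhglmOptions):
    """Block-diagonal fixed design and shared random-term codes."""
    x_mean, names_mean = build_fixed_design(data, list(options.fixed_mean))
    x_var, names_var = build_fixed_design(data, list(options.fixed_var))
    n = len(data)
    X = np.zeros((2 * n, x_mean.shape[1] + x_var.shape[1]))
    X[:n, : x_mean.shape[1]] = x_mean
    X[n:, x_mean.shape[1] :] = x_var
    animal_codes = ped.index_of(data["sow"].to_numpy())
    sows, sow_codes = np.unique(data["sow"].to_numpy(), return_inverse=True)
    traits = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    return X, names_mean + names_var, animal_codes, sows, sow_codes, traits


def dhglm_update(
    state: DhglmState,
    data: pd.DataFrame,
    ped: Pedigree,
    options: DhglmOptions | None = None,
) -> DhglmState:
    """One DHGLM cycle: joint weighted bivariate REML fit + psi/W refresh."""
    options = options or DhglmOptions()
    if np.max(np.abs(state.psi)) > options.psi_abort:
        raise ConvergenceError(
            f"DHGLM diverged: |psi| exceeded {options.psi_abort}"
        )
    X, _, animal_codes, sows, sow_codes, traits = _joint_design(data, ped, options)
    n = len(data)
    y_joint = np.concatenate([data["tnb"].to_numpy(dtype=float), state.psi])
    weights = np.concatenate([state.w_mean, state.w_var])
    codes2 = np.concatenate([animal_codes, animal_codes])
    sow2 = np.concatenate([sow_codes, sow_codes])
    terms = [
        RandomTerm(
            "additive",
            codes2,
            ped.n,
            kinv=ped.a_inverse(),
            logdet_k=ped.logdet_a,
            cov=state.g_cov,
        ),
        RandomTerm("permanent_env", sow2, len(sows), cov=state.pe_cov),
    ]
    core = reml_fit(
        y_joint,
        X,
        terms,
        traits=traits,
        n_traits=2,
        resid_group=traits,
        weights=weights,
        resid_start=state.scaling,
        estimate=True,
        max_iter=options.reml_iters_per_cycle,
        em_iters=1,
        raise_on_maxiter=False,
    )
    # predicted log residual variance for every TNB record = the fitted
    # variance-part linear predictor of that record's psi row, under-relaxed
    # to damp the two-cycle oscillation of the reweighting map
    zeta = options.damping * core.fitted[n:] + (1.0 - options.damping) * state.zeta
    e = core.residuals[:n]
    h = np.clip(core.leverage[:n], 0.0, 1.0 - 1e-8)
    d = np.maximum(e**2, PSI_EPS) / (1.0 - h)
    ez = np.exp(zeta)
    psi = zeta + (d - ez) / ez
    return DhglmState(
        cycle=state.cycle + 1,
        psi=psi,
        zeta=zeta,
        w_mean=np.exp(-zeta),
        w_var=(1.0 - h) / 2.0,
        g_cov=core.cov["additive"].copy(),
        pe_cov=core.cov["permanent_env"].copy(),
        scaling=core.resid_var.copy(),
        resid_mean=e,
        leverage_mean=h,
        ebv=core.u["additive"].copy(),
        pev=core.pev["additive"].copy(),
        pe_sol=core.u["permanent_env"].copy(),
        beta=core.beta.copy(),
        loglik=core.loglik,
        param_cov=core.param_cov,
        cov_se={k: v.copy() for k, v in core.cov_se.items()},
        resid_se=core.resid_se.copy(),
    )


def _corr_and_se(cov2: np.ndarray, block: np.ndarray | None):
    v1, c, v2 = cov2[0, 0], cov2[0, 1], cov2[1, 1]
    denom = math.sqrt(max(v1 * v2, 1e-300))
    r = float(np.clip(c / denom, -1.0, 1.0))
    if block is None:
        return r, float("nan")
    grad = np.array([-0.5 * r / v1, 1.0 / denom, -0.5 * r / v2])
    var = float(grad @ block @ grad)
    return r, math.sqrt(max(var, 0.0))


def run_dhglm(
    data: pd.DataFrame,
    ped: Pedigree,
    options: DhglmOptions | None = None,
    mean_fit: MixedModelFit | None = None,
    **mean_fit_kwargs,
) -> DhglmResult:
    """Iterate the DHGLM to convergence on an edited record table.

    Convergence requires the largest relative change of all variance
    components to fall below ``tol_components`` and the correlation between
    successive variance-part EBV vectors to exceed ``1 - tol_ebv``.
    """
    options = options or DhglmOptions()
    if mean_fit is None:
        spec = ModelSpec(
            response="tnb",
            fixed=list(options.fixed_mean),
            random=["additive", "permanent_env"],
            animal="sow",
        )
        mean_fit = fit_mixed_model(spec, data, ped, **mean_fit_kwargs)
    state = initialize_dhglm(mean_fit, options)
    trace = []
    converged = False
    prev_ebv = None
    for _ in range(options.max_cycles):
        prev = _pack(state)
        state = dhglm_update(state, data, ped, options)
        cur = _pack(state)
        rel = float(np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-6)))
        ebv_v = state.ebv[1]
        if prev_ebv is not None and np.std(ebv_v) > 0 and np.std(prev_ebv) > 0:
            ebv_corr = float(np.corrcoef(ebv_v, prev_ebv)[0, 1])
        else:
            ebv_corr = 0.0
        prev_ebv = ebv_v.copy()
        trace.append(
            {
                "cycle": state.cycle,
                "loglik": state.loglik,
                "rel_change": rel,
                "ebv_corr": ebv_corr,
                "g_cov": state.g_cov.copy(),
                "pe_cov": state.pe_cov.copy(),
                "scaling": state.scaling.copy(),
            }
        )
        if rel < options.tol_components and ebv_corr > 1.0 - options.tol_ebv:
            converged = True
            break
    if not converged and options.max_cycles > 1:
        raise ConvergenceError(
            f"DHGLM did not converge in {options.max_cycles} cycles", trace=trace
        )

    pcov = state.param_cov
    # engine parameter order: additive (0,0),(0,1),(1,1); pe likewise; resid
    r_a, r_a_se = _corr_and_se(state.g_cov, pcov[0:3, 0:3] if pcov is not None else None)
    r_pe, r_pe_se = _corr_and_se(state.pe_cov, pcov[3:6, 3:6] if pcov is not None else None)
    idx = pd.Index(ped.ids, name="animal")
    return DhglmResult(
        state=state,
        ebv_mean=pd.Series(state.ebv[0], index=idx),
        ebv_var=pd.Series(state.ebv[1], index=idx),
        pev_mean=pd.Series(state.pev[0], index=idx),
        pev_var=pd.Series(state.pev[1], index=idx),
        psi_hat=state.zeta,
        g_cov=state.g_cov,
        pe_cov=state.pe_cov,
        g_cov_se=state.cov_se["additive"],
        pe_cov_se=state.cov_se["permanent_env"],
        scaling=state.scaling,
        scaling_se=state.resid_se,
        r_a_av=r_a,
        r_a_av_se=r_a_se,
        r_pe_pev=r_pe,
        r_pe_pev_se=r_pe_se,
        n_cycles=state.cycle,
        converged=converged,
        trace=trace,
    )


def _pack(state: DhglmState) -> np.ndarray:
    return np.array(
        [
            state.g_cov[0, 0],
            state.g_cov[0, 1],
            state.g_cov[1, 1],
            state.pe_cov[0, 0],
            state.pe_cov[0, 1],
            state.pe_cov[1, 1],
            state.scaling[0],
            state.scaling[1],
        ]
    )
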
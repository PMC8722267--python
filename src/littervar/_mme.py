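"""Sparse mixed-model-equations engine: BLUP solutions and AI-REML.

Henderson's mixed-model equations are assembled sparsely for an arbitrary
number of random terms, each with covariance ``G0 (t x t) \\otimes K`` where
``K`` is a known structure matrix given by its sparse inverse (pedigree
A-inverse, or identity), and a diagonal residual ``R = diag(sigma2[g_j]/w_j)``
with free per-group variances and known per-record weights.  Multi-trait
(stacked) systems use a per-record trait index; random-term columns are laid
out trait-major so the precision contribution is ``kron(G0^-1, K^-1)``.

Variance components are estimated by average-information REML.  The first
iterations take EM steps (globally convergent, guarantees PSD updates); later
iterations take AI (Newton-type) steps with step halving and an EM fallback
whenever a step leaves the parameter space.  The gradient uses the standard
MME identities

    tr(P Z (E \\otimes K) Z') = q tr(G0^-1 E) - tr((G0^-1 E G0^-1 \\otimes K^-1) Cuu)
    y'P Z (E \\otimes K) Z' P y = u_hat' (G0^-1 E G0^-1 \\otimes K^-1) u_hat

so only the inverse of the sparse coefficient matrix is needed; it is
obtained column-wise from a SuperLU factorisation and reused for prediction
error variances and hat-matrix leverages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigurationError, ConvergenceError, SingularDesignError

__all__ = ["RandomTerm", "CoreFit", "reml_fit"]

_FLOOR = 1e-10


@dataclass
class RandomTerm:
    """One random effect: per-record level codes plus covariance structure."""

    name: str
    codes: np.ndarray            # level index per record, 0..n_levels-1
    n_levels: int
    kinv: sp.spmatrix | None = None   # None means identity structure
    logdet_k: float = 0.0
    cov: np.ndarray | float = 1.0     # starting t x t covariance (or scalar)

    def cov0(self, n_traits: int) -> np.ndarray:
        c = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if c.shape != (n_traits, n_traits):
            if c.size == 1:
                c = np.eye(n_traits) * float(c.ravel()[0])
            else:
                raise ConfigurationError(
                    f"term {self.name}: start covariance shape {c.shape} "
                    f"does not match {n_traits} trait(s)"
                )
        return c.copy()


@dataclass
class CoreFit:
    """Converged (or single-pass) mixed-model fit at engine level."""

    beta: np.ndarray
    u: dict
    cov: dict                   # term name -> t x t covariance matrix
    cov_se: dict
    resid_var: np.ndarray       # per residual group
    resid_se: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    pev: dict                   # term name -> (t, q) prediction error variances
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(repr=False, default_factory=list)
    param_names: list = field(default_factory=list)
    param_cov: np.ndarray | None = None
    beta_se: np.ndarray | None = None


def _check_rank(X: np.ndarray):
    gram = X.T @ X
    ev = np.linalg.eigvalsh(gram)
    if ev[0] < 1e-9 * max(ev[-1], 1.0):
        # identify aliased columns via pivoted QR on the Gram matrix
        from scipy.linalg import qr

        _, r, piv = qr(gram, pivoting=True)
        d = np.abs(np.diag(r))
        aliased = piv[d < 1e-9 * max(d.max(), 1.0)]
        raise SingularDesignError(
            f"fixed-effect design is rank deficient (aliased columns {sorted(aliased)})",
            aliased=aliased,
        )


def _pad_rows(T: sp.csr_matrix):
    """Row pattern of T padded to rectangular arrays for leverage gathers."""
    n = T.shape[0]
    nnz = np.diff(T.indptr)
    k = int(nnz.max()) if n else 0
    cols = np.zeros((n, k), dtype=np.int64)
    vals = np.zeros((n, k))
    rows = np.repeat(np.arange(n), nnz)
    within = np.arange(T.nnz) - np.repeat(T.indptr[:-1], nnz)
    cols[rows, within] = T.indices
    vals[rows, within] = T.data
    return cols, vals


def _hat_diag(cols, vals, cinv):
    """diag(T C^-1 T') from the padded row pattern of T."""
    k = cols.shape[1]
    out = np.zeros(cols.shape[0])
    for a in range(k):
        for b in range(k):
            out += vals[:, a] * vals[:, b] * cinv[cols[:, a], cols[:, b]]
    return out


def _dense_inverse(lu, m, chunk=1024):
    out = np.empty((m, m))
    eye = np.zeros((m, min(chunk, m)))
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        block = eye[:, : j1 - j0]
        block[:] = 0.0
        block[np.arange(j0, j1), np.arange(j1 - j0)] = 1.0
        out[:, j0:j1] = lu.solve(block)
    return 0.5 * (out + out.T)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    *,
    traits: np.ndarray | None = None,
    n_traits: int = 1,
    resid_group: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    resid_start: np.ndarray | float = 1.0,
    estimate: bool = True,
    max_iter: int = 50,
    em_iters: int = 2,
    tol_loglik: float = 1e-8,
    tol_comp: float = 1e-6,
    raise_on_maxiter: bool = True,
    verbose: bool = False,
) -> CoreFit:
    """Fit (or solve at fixed components) the sparse mixed model.

    With ``estimate=False`` a single BLUP/GLS pass at the supplied variance
    components is performed; otherwise AI-REML runs until the change in the
    restricted log-likelihood is below ``tol_loglik`` and the largest relative
    component change is below ``tol_comp``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise ConfigurationError("X must be (n_records, n_fixed)")
    _check_rank(X)
    p = X.shape[1]
    traits = np.zeros(n, dtype=np.int64) if traits is None else np.asarray(traits)
    resid_group = (
        np.zeros(n, dtype=np.int64) if resid_group is None else np.asarray(resid_group)
    )
    n_groups = int(resid_group.max()) + 1 if n else 1
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ConfigurationError("weights must be strictly positive")

    covs = [t.cov0(n_traits) for t in terms]
    sigma2 = np.broadcast_to(np.asarray(resid_start, dtype=float), (n_groups,)).copy()
    if np.any(sigma2 <= 0):
        raise ConfigurationError("starting residual variances must be positive")

    # --- fixed sparse structure -------------------------------------- #
    blocks = [sp.csr_matrix(X)]
    offsets, qs = [], []
    off = p
    for t in terms:
        q = t.n_levels
        offsets.append(off)
        qs.append(q)
        cols = traits * q + np.asarray(t.codes, dtype=np.int64)
        blocks.append(
            sp.csr_matrix(
                (np.ones(n), (np.arange(n), cols)), shape=(n, n_traits * q)
            )
        )
        off += n_traits * q
    m = off
    T = sp.hstack(blocks, format="csr")
    Tt = T.T.tocsr()
    pad_cols, pad_vals = _pad_rows(T)
    group_masks = [resid_group == g for g in range(n_groups)]
    ngroup = np.array([msk.sum() for msk in group_masks])
    if np.any(ngroup == 0):
        raise ConfigurationError("empty residual group")

    # parameter bookkeeping
    param_names: list[str] = []
    cov_params: list[tuple[int, int, int]] = []
    if estimate:
        for it, t in enumerate(terms):
            for a in range(n_traits):
                for b in range(a, n_traits):
                    cov_params.append((it, a, b))
                    param_names.append(f"{t.name}[{a},{b}]" if n_traits > 1 else t.name)
        for g in range(n_groups):
            param_names.append(f"resid[{g}]" if n_groups > 1 else "resid")
    n_par = len(cov_params) + (n_groups if estimate else 0)

    def g_inv_block():
        parts = [sp.csr_matrix((p, p))]
        for cov, t in zip(covs, terms):
            g0inv = np.linalg.inv(cov)
            if t.kinv is None:
                parts.append(sp.kron(sp.csr_matrix(g0inv), sp.identity(t.n_levels)))
            else:
                parts.append(sp.kron(sp.csr_matrix(g0inv), t.kinv))
        return sp.block_diag(parts, format="csr")

    trace: list[dict] = []
    loglik_prev = -np.inf
    converged = not estimate
    n_iter = 0
    kinv_coo = [
        (t.kinv.tocoo() if t.kinv is not None else None) for t in terms
    ]

    state = {}
    for iteration in range(max_iter if estimate else 1):
        n_iter = iteration + 1
        rinv = weights / sigma2[resid_group]
        TtR = Tt.multiply(rinv[np.newaxis, :]).tocsr()
        C = (TtR @ T + g_inv_block()).tocsc()
        try:
            lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # singular MME
            raise SingularDesignError(f"mixed-model equations singular: {exc}")
        logdet_c = float(np.log(np.abs(lu.U.diagonal())).sum())
        rhs = TtR @ y
        sol = lu.solve(rhs)
        fitted = T @ sol
        e = y - fitted
        py = rinv * e
        ypy = float(y @ py)
        logdet_r = float(np.sum(np.log(sigma2[resid_group] / weights)))
        logdet_g = 0.0
        for cov, t in zip(covs, terms):
            sgn, ld = np.linalg.slogdet(cov)
            logdet_g += t.n_levels * ld + n_traits * t.logdet_k
        loglik = -0.5 * (logdet_r + logdet_g + logdet_c + ypy)

        cinv = _dense_inverse(lu, m)
        hat = _hat_diag(pad_cols, pad_vals, cinv)
        leverage = rinv * hat

        # per-term summaries
        S_list, Tmat_list, U_list = [], [], []
        for it, t in enumerate(terms):
            q, o = qs[it], offsets[it]
            U = sol[o : o + n_traits * q].reshape(n_traits, q)
            S = np.empty((n_traits, n_traits))
            Tm = np.empty((n_traits, n_traits))
            for a in range(n_traits):
                ka = t.kinv @ U[a] if t.kinv is not None else U[a]
                for b in range(a, n_traits):
                    S[a, b] = S[b, a] = float(ka @ U[b])
                    blk_a, blk_b = o + a * q, o + b * q
                    if t.kinv is None:
                        tm = float(
                            cinv[np.arange(blk_a, blk_a + q), np.arange(blk_b, blk_b + q)].sum()
                        )
                    else:
                        coo = kinv_coo[it]
                        tm = float(
                            (coo.data * cinv[blk_a + coo.row, blk_b + coo.col]).sum()
                        )
                    Tm[a, b] = Tm[b, a] = tm
            S_list.append(S)
            Tmat_list.append(Tm)
            U_list.append(U)

        state = {
            "lu": lu,
            "cinv": cinv,
            "sol": sol,
            "e": e,
            "py": py,
            "fitted": fitted,
            "leverage": leverage,
            "loglik": loglik,
            "U_list": U_list,
            "rinv": rinv,
            "TtR": TtR,
        }
        trace.append(
            {
                "iteration": iteration,
                "loglik": loglik,
                "cov": [c.copy() for c in covs],
                "resid_var": sigma2.copy(),
            }
        )
        if verbose:
            print(f"iter {iteration}: loglik={loglik:.6f}")

        if not estimate:
            converged = True
            break

        # ---- gradient ------------------------------------------------ #
        grad = np.zeros(n_par)
        F = np.zeros((n, n_par))
        for ip, (it, a, b) in enumerate(cov_params):
            t = terms[it]
            q = qs[it]
            g0inv = np.linalg.inv(covs[it])
            E = np.zeros((n_traits, n_traits))
            E[a, b] = E[b, a] = 1.0
            M = g0inv @ E @ g0inv
            tr_pv = q * float(np.sum(g0inv * E)) - float(np.sum(M * Tmat_list[it]))
            ypvpy = float(np.sum(M * S_list[it]))
            grad[ip] = -0.5 * (tr_pv - ypvpy)
            B = (E @ g0inv) @ U_list[it]          # (t, q)
            F[:, ip] = B[traits, terms[it].codes]
        for g in range(n_groups):
            msk = group_masks[g]
            tr_pd = float(np.sum(1.0 - leverage[msk])) / sigma2[g]
            ypdpy = float(np.sum(py[msk] ** 2 / weights[msk]))
            ip = len(cov_params) + g
            grad[ip] = -0.5 * (tr_pd - ypdpy)
            F[msk, ip] = py[msk] / weights[msk]

        # ---- average information ------------------------------------- #
        B = TtR @ F
        PF = rinv[:, np.newaxis] * (F - T @ lu.solve(B))
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)
        state["AI"] = AI

        # ---- parameter update ---------------------------------------- #
        def em_update():
            new_covs = [
                (S_list[i] + Tmat_list[i]) / qs[i] for i in range(len(terms))
            ]
            new_sig = np.array(
                [
                    float(np.sum(weights[msk] * e[msk] ** 2))
                    / max(float(np.sum(1.0 - leverage[msk])), 1e-8)
                    for msk in group_masks
                ]
            )
            return new_covs, new_sig

        def pack(cv, sg):
            vals = [cv[it][a, b] for (it, a, b) in cov_params]
            return np.array(vals + list(sg))

        def unpack(vec):
            cv = [c.copy() for c in covs]
            for ip, (it, a, b) in enumerate(cov_params):
                cv[it][a, b] = cv[it][b, a] = vec[ip]
            sg = np.array(vec[len(cov_params) :])
            return cv, sg

        def project(cv, sg):
            """Pull a proposal back into the parameter space: variances to
            the floor, covariances into the PSD cone."""
            sg = np.maximum(sg, _FLOOR * scale0)
            for c in cv:
                np.fill_diagonal(c, np.maximum(np.diag(c), _FLOOR * scale0))
                for a in range(n_traits):
                    for b in range(a + 1, n_traits):
                        bound = 0.98 * np.sqrt(c[a, a] * c[b, b])
                        c[a, b] = c[b, a] = np.clip(c[a, b], -bound, bound)
            return cv, sg

        scale0 = max(float(np.max(np.abs(pack(covs, sigma2)))), 1e-8)
        theta = pack(covs, sigma2)
        floor_val = _FLOOR * scale0
        # active set: variances held at the zero boundary (gradient pointing
        # outward) are pinned, together with their covariances, so repeated
        # propose-and-clip cycles cannot jitter the free parameters
        pinned = np.zeros(n_par, dtype=bool)
        diag_pinned = {}
        for ip, (it, a, b) in enumerate(cov_params):
            if a == b and covs[it][a, a] <= 2.0 * floor_val and grad[ip] <= 0.0:
                pinned[ip] = True
                diag_pinned[(it, a)] = True
        for ip, (it, a, b) in enumerate(cov_params):
            if a != b and (diag_pinned.get((it, a)) or diag_pinned.get((it, b))):
                pinned[ip] = True
        for g in range(n_groups):
            ip = len(cov_params) + g
            if sigma2[g] <= 2.0 * floor_val and grad[ip] <= 0.0:
                pinned[ip] = True
        free = ~pinned
        stepped = False
        if iteration >= em_iters and free.any():
            try:
                delta = np.zeros(n_par)
                sub = AI[np.ix_(free, free)]
                delta[free] = np.linalg.solve(
                    sub + 1e-10 * scale0 * np.eye(int(free.sum())), grad[free]
                )
                # pinned covariances are driven to exactly zero
                for ip, (it, a, b) in enumerate(cov_params):
                    if pinned[ip] and a != b:
                        delta[ip] = -theta[ip]
                # trust region: no parameter moves more than half its size
                # (or a modest fraction of the dominant component)
                cap = np.maximum(0.5 * np.abs(theta), 0.05 * scale0)
                cap[pinned] = np.inf
                delta = np.clip(delta, -cap, cap)
                new_covs, new_sigma2 = project(*unpack(theta + delta))
                stepped = True
            except np.linalg.LinAlgError:
                pass
        if not stepped:
            new_covs, new_sigma2 = project(*em_update())

        old = pack(covs, sigma2)
        new = pack(new_covs, new_sigma2)
        # components far below the dominant one are measured on its scale,
        # so a variance pinned at the boundary cannot block convergence
        rel = np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-3 * scale0))
        covs, sigma2 = new_covs, new_sigma2
        dll = loglik - loglik_prev
        loglik_prev = loglik
        if iteration > em_iters and abs(dll) < tol_loglik and rel < tol_comp:
            converged = True
            break

    if estimate and not converged and raise_on_maxiter:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trace=trace
        )

    # --- standard errors from the AI matrix at the final estimates ---- #
    cov_se = {t.name: np.full((n_traits, n_traits), np.nan) for t in terms}
    resid_se = np.full(n_groups, np.nan)
    param_cov = None
    if estimate and n_par:
        AI = state.get("AI")
        try:
            param_cov = np.linalg.inv(AI)
            se = np.sqrt(np.maximum(np.diag(param_cov), 0.0))
            for ip, (it, a, b) in enumerate(cov_params):
                cov_se[terms[it].name][a, b] = cov_se[terms[it].name][b, a] = se[ip]
            resid_se = se[len(cov_params) :].copy()
        except np.linalg.LinAlgError:
            pass

    cinv = state["cinv"]
    pev = {}
    u_out = {}
    for it, t in enumerate(terms):
        q, o = qs[it], offsets[it]
        u_out[t.name] = state["sol"][o : o + n_traits * q].reshape(n_traits, q)
        idx = np.arange(o, o + n_traits * q)
        pev[t.name] = cinv[idx, idx].reshape(n_traits, q)

    beta = state["sol"][:p]
    beta_se = np.sqrt(np.maximum(cinv[np.arange(p), np.arange(p)], 0.0))
    return CoreFit(
        beta=beta,
        u=u_out,
        cov={t.name: c for t, c in zip(terms, covs)},
        cov_se=cov_se,
        resid_var=sigma2,
        resid_se=resid_se,
        residuals=state["e"],
        fitted=state["fitted"],
        leverage=state["leverage"],
        pev=pev,
        loglik=state["loglik"],
        converged=converged,
        n_iter=n_iter,
        trace=trace,
        param_names=param_names,
        param_cov=param_cov,
        beta_se=beta_se,
    )
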
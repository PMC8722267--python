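"""Pedigree machinery and the mixed-model engine against dense oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from littervar._mme import RandomTerm, reml_fit
from littervar.animal_model import (
    ModelSpec,
    Pedigree,
    VarianceComponents,
    build_a_inverse,
    fit_mixed_model,
    heritability,
)
from littervar.errors import ConfigurationError, PedigreeError

from conftest import random_pedigree, tabular_a


# ------------------------------------------------------------------ #
# pedigree / A-inverse
# ------------------------------------------------------------------ #
class TestPedigree:
    def test_single_founder_a_inverse_is_identity(self):
        ped = Pedigree(np.array([1]), np.array([-1]), np.array([-1]))
        assert np.allclose(build_a_inverse(ped).toarray(), [[1.0]])

    def test_trio_a_inverse_matches_tabular_inverse(self, trio_pedigree):
        expected = [[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]
        assert np.allclose(build_a_inverse(trio_pedigree).toarray(), expected)

    def test_full_sibs_relationship_is_half(self):
        ped = Pedigree(
            np.arange(1, 5),
            np.array([-1, -1, 0, 0]),
            np.array([-1, -1, 1, 1]),
        )
        A = tabular_a(ped.sire, ped.dam)
        assert A[2, 3] == pytest.approx(0.5)
        assert np.allclose(build_a_inverse(ped).toarray() @ A, np.eye(4), atol=1e-10)

    def test_a_inverse_and_inbreeding_match_tabular_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            ped = random_pedigree(rng, 5, 20)
            A = tabular_a(ped.sire, ped.dam)
            assert np.allclose(ped.inbreeding, np.diag(A) - 1.0, atol=1e-12)
            assert np.allclose(
                build_a_inverse(ped).toarray() @ A, np.eye(ped.n), atol=1e-8
            )
            sign, logdet = np.linalg.slogdet(A)
            assert ped.logdet_a == pytest.approx(logdet, abs=1e-9)

    def test_cycle_detection(self):
        frame = pd.DataFrame(
            {"id": [1, 2, 3], "sire": [3, 1, 2], "dam": [0, 0, 0]}
        )
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_frame(frame)

    def test_offspring_before_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree(np.array([1, 2]), np.array([1, -1]), np.array([-1, -1]))

    def test_from_frame_reorders_parents_first(self):
        frame = pd.DataFrame(
            {"id": [3, 1, 2], "sire": [1, 0, 0], "dam": [2, 0, 0]}
        )
        ped = Pedigree.from_frame(frame)
        pos = {a: i for i, a in enumerate(ped.ids)}
        assert pos[1] < pos[3] and pos[2] < pos[3]


# ------------------------------------------------------------------ #
# BLUP equals dense GLS (property test)
# ------------------------------------------------------------------ #
def _dense_gls(y, X, Zs, Gs, rdiag):
    V = np.diag(rdiag)
    for Z, G in zip(Zs, Gs):
        V += Z @ G @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    us = [G @ Z.T @ Vi @ (y - X @ beta) for Z, G in zip(Zs, Gs)]
    return beta, us, Vi


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_blup_equals_dense_gls_oracle(seed):
    """MME solutions equal the dense GLS oracle on random small models."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, 4, 10)
    n = int(rng.integers(8, 30))
    codes = rng.integers(0, ped.n, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, 0.5]) + rng.normal(size=n) * 2.0
    s2a, s2pe = 1.3, 0.7
    grp = rng.integers(0, 2, n)
    s2e = np.array([2.0, 3.5])
    w = rng.uniform(0.5, 2.0, n)
    terms = [
        RandomTerm("a", codes, ped.n, kinv=ped.a_inverse(), logdet_k=ped.logdet_a, cov=s2a),
        RandomTerm("pe", codes % 3, 3, cov=s2pe),
    ]
    fit = reml_fit(
        y, X, terms, resid_group=grp, weights=w, resid_start=s2e, estimate=False
    )
    A = np.linalg.inv(ped.a_inverse().toarray())
    Za = np.zeros((n, ped.n))
    Za[np.arange(n), codes] = 1.0
    Zp = np.zeros((n, 3))
    Zp[np.arange(n), codes % 3] = 1.0
    beta, us, Vi = _dense_gls(y, X, [Za, Zp], [A * s2a, np.eye(3) * s2pe], s2e[grp] / w)
    assert np.allclose(fit.beta, beta, atol=1e-8)
    assert np.allclose(fit.u["a"][0], us[0], atol=1e-8)
    assert np.allclose(fit.u["pe"][0], us[1], atol=1e-8)
    # leverage diagonal equals the dense hat matrix diagonal
    R = np.diag(s2e[grp] / w)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    assert np.allclose(fit.leverage, np.diag(np.eye(n) - R @ P), atol=1e-8)


def test_leverage_sum_equals_hat_trace():
    """Sum of leverages equals the trace of the hat projection."""
    rng = np.random.default_rng(9)
    ped = random_pedigree(rng, 6, 12)
    n = 25
    codes = rng.integers(0, ped.n, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    terms = [RandomTerm("a", codes, ped.n, kinv=ped.a_inverse(), cov=1.0)]
    fit = reml_fit(y, X, terms, resid_start=2.0, estimate=False)
    A = np.linalg.inv(ped.a_inverse().toarray())
    Za = np.zeros((n, ped.n))
    Za[np.arange(n), codes] = 1.0
    V = Za @ A @ Za.T + 2.0 * np.eye(n)
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    H = np.eye(n) - 2.0 * P
    assert fit.leverage.sum() == pytest.approx(np.trace(H), abs=1e-8)


def test_reml_loglik_nondecreasing_under_em():
    """Pure EM iterations never decrease the restricted log-likelihood."""
    rng = np.random.default_rng(12)
    ngrp, per = 40, 4
    g = np.repeat(np.arange(ngrp), per)
    y = 1.0 + rng.normal(0, 1.2, ngrp)[g] + rng.normal(0, 1.0, ngrp * per)
    X = np.ones((len(y), 1))
    fit = reml_fit(
        y,
        X,
        [RandomTerm("u", g, ngrp, cov=0.3)],
        estimate=True,
        max_iter=25,
        em_iters=25,
        raise_on_maxiter=False,
    )
    lls = [t["loglik"] for t in fit.trace]
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_pev_shrinks_with_more_records_per_sow():
    """Balanced designs: more repeated records give smaller PEV."""
    rng = np.random.default_rng(21)
    ped = Pedigree(np.arange(1, 21), np.full(20, -1), np.full(20, -1))
    pevs = []
    for reps in (2, 4, 8):
        codes = np.repeat(np.arange(20), reps)
        n = len(codes)
        y = rng.normal(size=n)
        fit = reml_fit(
            y,
            np.ones((n, 1)),
            [RandomTerm("a", codes, 20, kinv=ped.a_inverse(), cov=1.0)],
            resid_start=3.0,
            estimate=False,
        )
        pevs.append(fit.pev["a"][0].mean())
    assert pevs[0] > pevs[1] > pevs[2]


def test_model_without_random_terms_collapses_to_ols(small_dataset):
    _, ped, _, records, _ = small_dataset
    spec = ModelSpec(response="tnb", fixed=["parity"], random=[], animal="sow")
    fit = fit_mixed_model(spec, records, ped, max_iter=30)
    X = np.column_stack(
        [np.ones(len(records))]
        + [
            (records["parity"] == lev).to_numpy(dtype=float)
            for lev in sorted(records["parity"].unique())[1:]
        ]
    )
    beta_ols, *_ = np.linalg.lstsq(X, records["tnb"].to_numpy(), rcond=None)
    assert np.allclose(fit.fixed_effects.to_numpy(), beta_ols, atol=1e-6)


def test_reml_recovers_components_on_small_simulation(small_mean_fit):
    """REML point estimates stay within 3 SE of the generating values."""
    vc = small_mean_fit.varcomp
    assert abs(vc.sigma2_a - 1.33) < 3 * max(vc.se_a, 0.3) + 0.5
    assert abs(vc.sigma2_e_mean - 7.67) < 3 * max(vc.se_e[0], 0.3) + 0.5
    assert small_mean_fit.converged


# ------------------------------------------------------------------ #
# heritability
# ------------------------------------------------------------------ #
class TestHeritability:
    @pytest.mark.parametrize(
        "a, pe, e, expected",
        [
            (1.33, 0.86, 7.67, 0.135),
            (0.033, None, 1.33, 0.024),
            (0.037, 0.15, 0.84, 0.036),
            (0.0, 0.5, 1.0, 0.0),
        ],
    )
    def test_closed_form_values(self, a, pe, e, expected):
        assert heritability(a, pe, e) == pytest.approx(expected, abs=5e-4)

    def test_grouped_residual_uses_record_weighted_mean(self):
        vc = VarianceComponents(
            sigma2_a=1.0,
            sigma2_pe=None,
            sigma2_e=np.array([1.0, 3.0]),
            n_records_per_group=np.array([30, 10]),
        )
        assert vc.sigma2_e_mean == pytest.approx(1.5)
        assert heritability(vc) == pytest.approx(1.0 / 2.5)

    def test_zero_total_variance_raises(self):
        with pytest.raises(ConfigurationError):
            heritability(0.0, 0.0, 0.0)
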
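"""Dense whitening solver: closed forms, minimality, feasibility."""

import numpy as np
import pytest

from rkhsda import (
    KernelSpec,
    SolverConfig,
    assemble_N,
    build_mmd_operator,
    build_operator_set,
    compute_gram,
    solve_subspace,
)
from .conftest import random_bundle


def k_orthonormalize(W, K, rng):
    """Gram–Schmidt in the K-metric, restarting on near-dependence."""
    d = W.shape[1]
    Q = np.empty_like(W)
    for j in range(d):
        v = W[:, j]
        for i in range(j):
            v = v - (Q[:, i] @ K @ v) * Q[:, i]
        norm = np.sqrt(v @ K @ v)
        while norm < 1e-8:
            v = rng.standard_normal(W.shape[0])
            for i in range(j):
                v = v - (Q[:, i] @ K @ v) * Q[:, i]
            norm = np.sqrt(v @ K @ v)
        Q[:, j] = v / norm
    return Q


def principal_angle_cos(W1, W2):
    Q1, _ = np.linalg.qr(W1)
    Q2, _ = np.linalg.qr(W2)
    return np.linalg.svd(Q1.T @ Q2, compute_uv=False)


def test_assemble_N_limits(gram, bundle):
    ops = build_operator_set(gram, bundle.ys, bundle.Ns, bundle.Nt)
    N0 = assemble_N(ops, SolverConfig(lam=0.0, mu=0.0, d=2))
    np.testing.assert_allclose(N0, ops.L, atol=1e-14)
    Nmat = assemble_N(ops, SolverConfig(lam=0.7, mu=0.3, d=2))
    assert np.max(np.abs(Nmat - Nmat.T)) < 1e-12


def test_identity_objective_closed_form(gram):
    # With N = I the whitened matrix is Σ^{-1}, so the minimum trace is
    # the sum of reciprocals of the d largest eigenvalues of K.
    d = 3
    sm = solve_subspace(gram, np.eye(gram.n_samples), d)
    expected = np.sum(1.0 / gram.eigvals[:d])
    assert sm.objective == pytest.approx(expected, rel=1e-8)


def test_rank_one_mmd_annihilated(shift_problem):
    bundle, _ = shift_problem
    gm = compute_gram(bundle.X)
    L = build_mmd_operator(gm, bundle.Ns, bundle.Nt)
    sm = solve_subspace(gm, L, 4)
    # L has rank 1, so a 4-dim K-orthonormal subspace orthogonal to it exists
    assert sm.objective < 1e-8
    mmd2 = float(np.trace(sm.W.T @ L @ sm.W))
    assert mmd2 < 1e-8


def test_constraint_satisfied_and_objective_equals_eigsum(gram, bundle):
    ops = build_operator_set(gram, bundle.ys, bundle.Ns, bundle.Nt)
    sm = solve_subspace(gram, assemble_N(ops, SolverConfig(lam=1.0, mu=0.1, d=3)), 3)
    assert sm.constraint_residual < 1e-8
    assert sm.objective == pytest.approx(np.sum(sm.M_eigvals), abs=1e-8)
    assert np.all(np.diff(sm.M_eigvals) >= -1e-12)  # ascending


@pytest.mark.parametrize("trial", range(3))
def test_minimality_against_random_feasible_candidates(trial):
    rng = np.random.default_rng(200 + trial)
    b = random_bundle(rng, Ns=12, Nt=10, D=3)
    gm = compute_gram(b.X, KernelSpec("rbf", 1.0))
    ops = build_operator_set(gm, b.ys, b.Ns, b.Nt)
    Nmat = assemble_N(ops, SolverConfig(lam=0.5, mu=0.05, d=3))
    sm = solve_subspace(gm, Nmat, 3)
    Kj = gm.K + gm.jitter * np.eye(gm.n_samples)
    for _ in range(100):
        W0 = k_orthonormalize(rng.standard_normal((b.N, 3)), Kj, rng)
        assert sm.objective <= np.trace(W0.T @ Nmat @ W0) + 1e-10


def test_scale_equivariance(gram, bundle):
    ops = build_operator_set(gram, bundle.ys, bundle.Ns, bundle.Nt)
    Nmat = assemble_N(ops, SolverConfig(lam=0.5, mu=0.1, d=2))
    sm1 = solve_subspace(gram, Nmat, 2)
    sm2 = solve_subspace(gram, 3.5 * Nmat, 2)
    assert sm2.objective == pytest.approx(3.5 * sm1.objective, rel=1e-10)
    cos = principal_angle_cos(sm1.W, sm2.W)
    assert np.all(np.arccos(np.clip(cos, -1, 1)) < 1e-6)


def test_smallest_eigenvalues_beat_largest(gram, bundle):
    ops = build_operator_set(gram, bundle.ys, bundle.Ns, bundle.Nt)
    Nmat = assemble_N(ops, SolverConfig(lam=1.0, mu=0.1, d=2))
    sm = solve_subspace(gram, Nmat, 2)
    # flipping to the d largest whitened eigenvalues strictly increases the trace
    sm_full = solve_subspace(gram, Nmat, gram.n_samples)
    largest = np.sum(sm_full.M_eigvals[-2:])
    assert sm.objective < largest


def test_solver_errors(gram):
    with pytest.raises(ValueError):
        solve_subspace(gram, np.eye(gram.n_samples), gram.n_samples + 1)
    A = np.zeros((gram.n_samples, gram.n_samples))
    A[0, 1] = 1.0  # grossly asymmetric
    with pytest.raises(ValueError):
        solve_subspace(gram, A, 2)


def test_sign_convention_deterministic(gram, bundle):
    ops = build_operator_set(gram, bundle.ys, bundle.Ns, bundle.Nt)
    Nmat = assemble_N(ops, SolverConfig(lam=1.0, mu=0.1, d=3))
    W1 = solve_subspace(gram, Nmat, 3).W
    W2 = solve_subspace(gram, Nmat, 3).W
    np.testing.assert_array_equal(W1, W2)
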
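"""Operator construction checked against explicit projection-space oracles.

The oracle path never touches the operator matrices: it projects every
sample via y_i = Wᵀ K_iCol and computes the MMD / scatter definitions
directly on the projected points.
"""

import numpy as np
import pytest

from rkhsda import (
    KernelSpec,
    build_mmd_operator,
    build_scatter_operators,
    combine,
    compute_gram,
)
from .conftest import random_bundle


def projected(gm, W):
    return gm.K @ W  # row i is y_i = Wᵀ K_iCol


def direct_mmd2(Y, Ns):
    return float(np.sum((Y[:Ns].mean(axis=0) - Y[Ns:].mean(axis=0)) ** 2))


def direct_scatters(Y, ys, Ns):
    Ysrc = Y[:Ns]
    grand = Ysrc.mean(axis=0)
    sw = sb = 0.0
    for c in np.unique(ys):
        yc = Ysrc[ys == c]
        center = yc.mean(axis=0)
        sw += np.sum((yc - center) ** 2) / Ns
        sb += len(yc) / Ns * np.sum((center - grand) ** 2)
    return sw, sb


@pytest.mark.parametrize("trial", range(5))
def test_quadratic_forms_match_projection_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    b = random_bundle(rng, Ns=14, Nt=10, D=3, C=3)
    gm = compute_gram(b.X, KernelSpec("rbf", 1.2))
    W = rng.standard_normal((b.N, 3))
    Y = projected(gm, W)

    L = build_mmd_operator(gm, b.Ns, b.Nt)
    Phi, Psi = build_scatter_operators(gm, b.ys)
    sw, sb = direct_scatters(Y, b.ys, b.Ns)
    assert np.trace(W.T @ L @ W) == pytest.approx(direct_mmd2(Y, b.Ns), abs=1e-10)
    assert np.trace(W.T @ Phi @ W) == pytest.approx(sw, abs=1e-10)
    assert np.trace(W.T @ Psi @ W) == pytest.approx(sb, abs=1e-10)


def test_mmd_operator_is_rank_one_and_psd(gram, bundle):
    L = build_mmd_operator(gram, bundle.Ns, bundle.Nt)
    assert np.linalg.matrix_rank(L, tol=1e-10) <= 1
    assert np.linalg.eigvalsh(L).min() > -1e-10


def test_identical_domains_give_zero_mmd_operator(rng):
    X = rng.standard_normal((6, 3))
    b = combine(X, [1, 2, 3, 1, 2, 3], X)
    gm = compute_gram(b.X, KernelSpec("rbf", 1.0))
    L = build_mmd_operator(gm, 6, 6)
    assert np.max(np.abs(L)) < 1e-12


def test_single_class_gives_zero_between_scatter(rng):
    b = combine(rng.standard_normal((5, 3)), [1] * 5, rng.standard_normal((4, 3)))
    gm = compute_gram(b.X, KernelSpec("rbf", 1.0))
    _, Psi = build_scatter_operators(gm, b.ys)
    assert np.max(np.abs(Psi)) < 1e-12


def test_singleton_classes_give_zero_within_scatter(rng):
    b = combine(rng.standard_normal((4, 3)), [1, 2, 3, 4], rng.standard_normal((3, 3)))
    gm = compute_gram(b.X, KernelSpec("rbf", 1.0))
    Phi, _ = build_scatter_operators(gm, b.ys)
    assert np.max(np.abs(Phi)) < 1e-12


def test_scatter_operators_symmetric_psd(gram, bundle):
    Phi, Psi = build_scatter_operators(gram, bundle.ys)
    for M in (Phi, Psi):
        assert np.max(np.abs(M - M.T)) < 1e-10
        assert np.linalg.eigvalsh(M).min() > -1e-10


def test_grand_mean_identity(gram, bundle):
    # Σ_c (Nc/Ns) mean-column_c equals the grand source-column mean
    cols = gram.K[:, : bundle.Ns]
    grand = cols.mean(axis=1)
    acc = np.zeros_like(grand)
    for c in np.unique(bundle.ys):
        mask = bundle.ys == c
        acc += mask.sum() / bundle.Ns * cols[:, mask].mean(axis=1)
    np.testing.assert_allclose(acc, grand, atol=1e-12)


def test_source_permutation_equivariance(rng):
    b = random_bundle(rng, Ns=10, Nt=6, D=3, C=2)
    gm = compute_gram(b.X, KernelSpec("rbf", 1.1))
    perm_src = rng.permutation(b.Ns)
    perm = np.concatenate([perm_src, np.arange(b.Ns, b.N)])
    b2 = combine(b.Xs[perm_src], b.ys[perm_src], b.Xt)
    gm2 = compute_gram(b2.X, KernelSpec("rbf", 1.1))
    Phi, Psi = build_scatter_operators(gm, b.ys)
    Phi2, Psi2 = build_scatter_operators(gm2, b2.ys)
    np.testing.assert_allclose(Phi2, Phi[np.ix_(perm, perm)], atol=1e-10)
    np.testing.assert_allclose(Psi2, Psi[np.ix_(perm, perm)], atol=1e-10)


def test_operator_errors(gram):
    with pytest.raises(ValueError):
        build_mmd_operator(gram, 0, gram.n_samples)
    with pytest.raises(ValueError):
        build_mmd_operator(gram, 3, 3)
    with pytest.raises(ValueError):
        build_scatter_operators(gram, np.array([1, 3, 3]))  # class 2 absent
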
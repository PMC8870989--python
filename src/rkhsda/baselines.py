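"""Transfer component analysis (TCA) baseline and the scatter augmentation.

TCA minimizes tr(Wᵀ(KLK + μI)W) subject to WᵀKHKW = I_d, where H is the
centering matrix and L the MMD coefficient matrix with entries 1/Ns for
source, −1/Nt for target.  Since that L is the outer product e·eᵀ of the
signed indicator vector e, KLK = (Ke)(Ke)ᵀ equals the column-convention
rank-one MMD operator used by the core solvers, so the same whitening
machinery applies with constraint matrix KHK.

``augment_with_slda`` adds the source scatter term λ(Φ−Ψ) to any
baseline's quadratic objective, which is how baseline "+SLDA" variants
are formed.
"""

from __future__ import annotations

import numpy as np

from .kernels import GramModel
from .operators import OperatorSet
from .solver_dense import SubspaceModel, whitened_trace_min

__all__ = ["centering_matrix", "mmd_coefficient_vector", "solve_tca", "augment_with_slda"]


def centering_matrix(N: int) -> np.ndarray:
    """H = I − (1/N)·11ᵀ; symmetric, idempotent, annihilates constants."""
    return np.eye(N) - np.full((N, N), 1.0 / N)


def mmd_coefficient_vector(Ns: int, Nt: int) -> np.ndarray:
    """Signed indicator e with e_i = 1/Ns (source rows), −1/Nt (target rows)."""
    return np.concatenate([np.full(Ns, 1.0 / Ns), np.full(Nt, -1.0 / Nt)])


def solve_tca(
    gm: GramModel,
    Ns: int,
    Nt: int,
    mu: float,
    d: int,
    extra_quadratic: np.ndarray | None = None,
) -> SubspaceModel:
    """Solve the TCA trace minimization under the KHK constraint.

    Parameters
    ----------
    gm
        Gram model of the combined data.
    Ns, Nt
        Domain sizes (Ns + Nt = N).
    mu
        Ridge weight on tr(WᵀW).
    d
        Subspace dimension; must not exceed the numerical rank of KHK
        (at most N−1, since H annihilates the constant vector).
    extra_quadratic
        Optional symmetric N×N matrix added to the objective — the hook
        the "+SLDA" augmentation uses.
    """
    N = gm.n_samples
    if Ns + Nt != N:
        raise ValueError(f"Ns + Nt = {Ns + Nt} does not match N = {N}")
    e = mmd_coefficient_vector(Ns, Nt)
    a = gm.K @ e
    Nmat = np.outer(a, a) + mu * np.eye(N)
    if extra_quadratic is not None:
        Nmat = Nmat + extra_quadratic
    Nmat = 0.5 * (Nmat + Nmat.T)

    H = centering_matrix(N)
    B = gm.K @ H @ gm.K
    B = 0.5 * (B + B.T)
    bvals, bvecs = np.linalg.eigh(B)
    jitter = 0.0
    floor = 1e-10 * max(np.trace(B) / N, np.finfo(float).tiny)
    if bvals[0] < floor:
        jitter = floor
        bvals = bvals + jitter
    order = np.argsort(bvals)[::-1]
    bvals = np.clip(bvals[order], 0.0, None)
    bvecs = bvecs[:, order]
    rank_floor = max(10.0 * jitter, bvals[0] * N * np.finfo(float).eps)

    W, mvals = whitened_trace_min(Nmat, bvecs, bvals, d, rank_floor)
    residual = float(np.linalg.norm(W.T @ (B + jitter * np.eye(N)) @ W - np.eye(d)))
    return SubspaceModel(
        W=W,
        d=d,
        objective=float(np.sum(mvals)),
        M_eigvals=mvals,
        constraint_residual=residual,
        meta={"solver": "tca", "mu": mu},
    )


def augment_with_slda(base_quadratic: np.ndarray, ops: OperatorSet, lam: float) -> np.ndarray:
    """Add the source scatter regularizer λ(Φ−Ψ) to a quadratic objective."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    Q = base_quadratic + lam * (ops.Phi - ops.Psi)
    return 0.5 * (Q + Q.T)
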
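"""Dense solver: constrained trace minimization by whitening.

Solves  min_W tr(Wᵀ N W)  s.t.  Wᵀ K W = I_d.

With K = U Σ Uᵀ (symmetric PD after jitter) substitute V = Σ^{1/2} Uᵀ W;
the constraint becomes VᵀV = I_d and the objective tr(Vᵀ M V) with
M = Σ^{-1/2} Uᵀ N U Σ^{-1/2}.  The minimizer stacks the d eigenvectors
of M with the smallest eigenvalues, and the achieved objective is the
sum of those eigenvalues.  N may be indefinite (the scatter term Φ−Ψ
usually is), so negative eigenvalues of M are legitimate and picked
first.

Eigendirections of K at or below the jitter floor carry essentially no
kernel mass; they are excluded from the search space, so the effective
dimension is the numerical rank r of K and the solver requires d ≤ r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import GramModel
from .operators import OperatorSet

__all__ = ["SolverConfig", "SubspaceModel", "assemble_N", "solve_subspace", "whitened_trace_min"]


@dataclass
class SolverConfig:
    """Hyperparameters shared by the dense and sparse solvers.

    Parameters
    ----------
    lam
        Weight λ of the scatter term Φ−Ψ in the dense objective.
    mu
        Ridge weight μ on tr(WᵀW).
    gamma
        Weight γ of Φ−Ψ in the sparse objective.
    lam_sparse
        Weight λ of the L2,1 row-sparsity term in the sparse objective.
    d
        Subspace dimension.
    tol
        Relative objective-change convergence tolerance of the sparse
        iteration.
    max_iter
        Iteration cap of the sparse solver.
    seed
        Seed for any randomized component (none in the solvers
        themselves; carried for pipeline reproducibility).
    """

    lam: float = 1.0
    mu: float = 0.1
    gamma: float = 0.01
    lam_sparse: float = 0.1
    d: int = 2
    tol: float = 1e-6
    max_iter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "gamma", "lam_sparse"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.d < 1:
            raise ValueError("d must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class SubspaceModel:
    """Learned coefficient matrix with solver metadata.

    ``W`` is N×d; ``objective`` is the achieved trace value, equal to the
    sum of ``M_eigvals`` (the d smallest eigenvalues of the whitened
    matrix); ``constraint_residual`` is ‖WᵀBW − I_d‖_F for the constraint
    matrix B the solver used (K here, KHK for TCA).
    """

    W: np.ndarray
    d: int
    objective: float
    M_eigvals: np.ndarray
    constraint_residual: float
    meta: dict = field(default_factory=dict)


def assemble_N(ops: OperatorSet, cfg: SolverConfig) -> np.ndarray:
    """Objective matrix N = L + λ(Φ−Ψ) + μI of the dense problem."""
    N = ops.L + cfg.lam * (ops.Phi - ops.Psi)
    if cfg.mu:
        N = N + cfg.mu * np.eye(N.shape[0])
    return 0.5 * (N + N.T)


def whitened_trace_min(
    Nmat: np.ndarray,
    eigvecs: np.ndarray,
    eigvals: np.ndarray,
    d: int,
    rank_floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize tr(WᵀNW) s.t. WᵀBW = I_d for B = eigvecs·diag(eigvals)·eigvecsᵀ.

    Only eigendirections with eigenvalue strictly above ``rank_floor``
    enter the search space.  Returns (W, d smallest eigenvalues of M,
    ascending).
    """
    asym = np.max(np.abs(Nmat - Nmat.T))
    scale = max(np.max(np.abs(Nmat)), 1.0)
    if asym > 1e-8 * scale:
        raise ValueError(f"objective matrix asymmetric beyond tolerance ({asym:.3e})")
    Nmat = 0.5 * (Nmat + Nmat.T)

    keep = eigvals > rank_floor
    r = int(np.count_nonzero(keep))
    if d > r:
        raise ValueError(f"requested d={d} exceeds effective rank {r} of the constraint matrix")
    Ur = eigvecs[:, keep]
    inv_sqrt = 1.0 / np.sqrt(eigvals[keep])

    M = (inv_sqrt[:, None] * (Ur.T @ Nmat @ Ur)) * inv_sqrt[None, :]
    M = 0.5 * (M + M.T)
    mvals, mvecs = np.linalg.eigh(M)  # ascending
    V = mvecs[:, :d]
    # sign convention: largest-magnitude entry of each column positive
    for j in range(d):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    W = Ur @ (inv_sqrt[:, None] * V)
    return W, mvals[:d]


def _rank_floor(gm: GramModel) -> float:
    # an order of magnitude above the jitter keeps the directions the
    # jitter manufactured out of the search space
    floor = 10.0 * gm.jitter if gm.jitter > 0 else 0.0
    return max(floor, gm.eigvals[0] * gm.n_samples * np.finfo(float).eps)


def solve_subspace(gm: GramModel, Nmat: np.ndarray, d: int) -> SubspaceModel:
    """Solve the K-orthonormal trace minimization for a given objective matrix.

    Parameters
    ----------
    gm
        Gram model providing K and its (jittered) eigendecomposition.
    Nmat
        Symmetric N×N objective matrix (any combination of L, Φ−Ψ, μI).
    d
        Subspace dimension, at most the numerical rank of K.

    Returns
    -------
    SubspaceModel with WᵀKW = I_d to high precision.
    """
    W, mvals = whitened_trace_min(Nmat, gm.eigvecs, gm.eigvals, d, _rank_floor(gm))
    Kj = gm.K + gm.jitter * np.eye(gm.n_samples)
    residual = float(np.linalg.norm(W.T @ Kj @ W - np.eye(d)))
    return SubspaceModel(
        W=W,
        d=d,
        objective=float(np.sum(mvals)),
        M_eigvals=mvals,
        constraint_residual=residual,
        meta={"solver": "dense"},
    )
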
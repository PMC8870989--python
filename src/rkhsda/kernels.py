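"""Gram matrices of the combined source+target sample set.

Every quantity in the subspace-learning pipeline is expressed through
columns of the kernel matrix ``K`` of the combined data, so this module
owns the kernel evaluation, the (jittered) eigendecomposition that the
whitening solvers reuse, and column access.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import pairwise_kernels

__all__ = ["KernelSpec", "GramModel", "compute_gram", "kernel_column", "median_bandwidth"]

#: relative jitter added to the diagonal when K is numerically singular,
#: as a fraction of trace(K)/N (the mean eigenvalue)
JITTER_REL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Choice of reproducing kernel.

    Parameters
    ----------
    name
        ``"linear"`` for k(x, y) = x·y or ``"rbf"`` for
        k(x, y) = exp(-‖x-y‖² / (2σ²)).
    bandwidth
        The σ of the RBF kernel.  Ignored for the linear kernel.  When
        ``None`` and an RBF kernel is requested, the median pairwise
        distance of the data is used.
    """

    name: str = "rbf"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.name!r}; expected 'linear' or 'rbf'")
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class GramModel:
    """Kernel matrix of the combined sample set with its eigendecomposition.

    ``K`` is the raw Gram matrix; ``eigvecs``/``eigvals`` decompose
    ``K + jitter·I`` (jitter is zero whenever K is already comfortably
    positive definite).  Eigenvalues are stored in descending order.
    """

    K: np.ndarray
    eigvecs: np.ndarray
    eigvals: np.ndarray
    jitter: float
    spec: KernelSpec = field(default_factory=KernelSpec)

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]


def median_bandwidth(X: np.ndarray) -> float:
    """Median of the nonzero pairwise Euclidean distances (RBF heuristic)."""
    d = pdist(np.asarray(X, dtype=float))
    d = d[d > 0]
    if d.size == 0:  # all points identical; any positive value works
        return 1.0
    return float(np.median(d))


def _kernel_matrix(X: np.ndarray, spec: KernelSpec) -> tuple[np.ndarray, KernelSpec]:
    if spec.name == "linear":
        return pairwise_kernels(X, metric="linear"), spec
    sigma = spec.bandwidth if spec.bandwidth is not None else median_bandwidth(X)
    spec = KernelSpec("rbf", sigma)
    K = pairwise_kernels(X, metric="rbf", gamma=1.0 / (2.0 * sigma**2))
    return K, spec


def compute_gram(X: np.ndarray, spec: KernelSpec | None = None) -> GramModel:
    """Build the Gram matrix of ``X`` and eigendecompose it.

    A diagonal jitter of ``1e-10 · trace(K)/N`` is added before the
    eigendecomposition whenever the smallest raw eigenvalue falls below
    that amount, so the inverse square root used by the whitening
    solvers is well defined even for rank-deficient kernels.

    Parameters
    ----------
    X
        N×D data matrix, samples as rows, N ≥ 2.
    spec
        Kernel specification; defaults to an RBF kernel with the median
        pairwise-distance bandwidth.

    Returns
    -------
    GramModel
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if spec is None:
        spec = KernelSpec()

    K, spec = _kernel_matrix(X, spec)
    K = 0.5 * (K + K.T)  # symmetrize away round-off

    eigvals, eigvecs = np.linalg.eigh(K)
    jitter_floor = JITTER_REL * np.trace(K) / K.shape[0]
    jitter = 0.0
    if eigvals[0] < jitter_floor:
        jitter = float(jitter_floor)
        eigvals = eigvals + jitter
    # eigh returns ascending order; store descending
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    return GramModel(K=K, eigvecs=eigvecs, eigvals=eigvals, jitter=jitter, spec=spec)


def kernel_column(gm: GramModel, i: int) -> np.ndarray:
    """Return the i-th column of K (1-based, matching the K_iCol notation)."""
    if not 1 <= i <= gm.n_samples:
        raise IndexError(f"column index {i} out of range 1..{gm.n_samples}")
    return gm.K[:, i - 1].copy()
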
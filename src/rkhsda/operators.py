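"""Quadratic-form operators: MMD matrix L, scatter matrices Φ and Ψ.

All three are N×N positive semidefinite matrices built from columns of
the combined Gram matrix, so that for a coefficient matrix W

* ``tr(WᵀLW)`` is the squared MMD between the projected domain means,
* ``tr(WᵀΦW)`` is the within-class scatter of the projected source data,
* ``tr(WᵀΨW)`` is the between-class scatter of the projected source data.

The scatter operators use only source columns (the target domain is
unlabeled), but the columns themselves are full length-N vectors, so Φ
and Ψ are conformable with L.  The grand center is the mean over the Ns
source columns, which keeps the usual LDA identity
Σ_c (Nc/Ns)·mean_c = grand_mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import GramModel

__all__ = ["OperatorSet", "build_mmd_operator", "build_scatter_operators", "build_operator_set"]


@dataclass
class OperatorSet:
    """The three quadratic-form matrices plus the class/grand column means."""

    L: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    class_col_means: np.ndarray  # C×N, row c is the mean source column of class c+1
    grand_col_mean: np.ndarray  # length N


def build_mmd_operator(gm: GramModel, Ns: int, Nt: int) -> np.ndarray:
    """Rank-one MMD operator L = a·aᵀ.

    ``a`` is the difference between the mean source kernel column and the
    mean target kernel column.
    """
    if Ns <= 0 or Nt <= 0:
        raise ValueError("Ns and Nt must be positive")
    if Ns + Nt != gm.n_samples:
        raise ValueError(f"Ns + Nt = {Ns + Nt} does not match N = {gm.n_samples}")
    a = gm.K[:, :Ns].mean(axis=1) - gm.K[:, Ns:].mean(axis=1)
    return np.outer(a, a)


def build_scatter_operators(gm: GramModel, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (Φ) and between-class (Ψ) scatter operators.

    Parameters
    ----------
    gm
        Gram model of the combined data; the first ``len(ys)`` columns
        are the source columns.
    ys
        Contiguous source labels in 1..C.

    Returns
    -------
    (Phi, Psi) : both N×N symmetric PSD.
    """
    ys = np.asarray(ys, dtype=int)
    Ns = len(ys)
    classes = np.unique(ys)
    C = classes.max()
    if not np.array_equal(classes, np.arange(1, C + 1)):
        raise ValueError("labels must be contiguous 1..C with every class present")

    cols = gm.K[:, :Ns]  # length-N source columns
    grand = cols.mean(axis=1)
    N = gm.n_samples
    Phi = np.zeros((N, N))
    Psi = np.zeros((N, N))
    class_means = np.empty((C, N))
    for c in range(1, C + 1):
        cc = cols[:, ys == c]
        Nc = cc.shape[1]
        mean_c = cc.mean(axis=1)
        class_means[c - 1] = mean_c
        dev_b = mean_c - grand
        Psi += (Nc / Ns) * np.outer(dev_b, dev_b)
        dev_w = cc - mean_c[:, None]
        Phi += dev_w @ dev_w.T / Ns
    Phi = 0.5 * (Phi + Phi.T)
    Psi = 0.5 * (Psi + Psi.T)
    return Phi, Psi


def build_operator_set(gm: GramModel, ys: np.ndarray, Ns: int, Nt: int) -> OperatorSet:
    """Convenience constructor for all three operators at once."""
    L = build_mmd_operator(gm, Ns, Nt)
    Phi, Psi = build_scatter_operators(gm, ys)
    cols = gm.K[:, :Ns]
    ys = np.asarray(ys, dtype=int)
    C = int(ys.max())
    class_means = np.vstack([cols[:, ys == c].mean(axis=1) for c in range(1, C + 1)])
    return OperatorSet(
        L=L,
        Phi=Phi,
        Psi=Psi,
        class_col_means=class_means,
        grand_col_mean=cols.mean(axis=1),
    )
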
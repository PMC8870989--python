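"""Projection into the learned subspace and KNN classification.

The projected coordinate of sample i is y_i = Wᵀ·K_iCol, i.e. the stack
of all projections is K·W row-split at Ns.  Target points are classified
by Euclidean K-nearest-neighbors against the projected source points,
with majority vote; vote ties go to the class of the single nearest
neighbor among the tied classes, which is deterministic given the input
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .kernels import GramModel
from .solver_dense import SubspaceModel

__all__ = ["ProjectedData", "project", "knn_predict"]


@dataclass
class ProjectedData:
    """Subspace coordinates of the source (Ys) and target (Yt) samples."""

    Ys: np.ndarray
    Yt: np.ndarray


def project(gm: GramModel, sm: SubspaceModel, Ns: int) -> ProjectedData:
    """Project all samples through the kernel columns: Y = K·W."""
    if sm.W.shape[0] != gm.n_samples:
        raise ValueError(
            f"W has {sm.W.shape[0]} rows but K is {gm.n_samples}×{gm.n_samples}"
        )
    if not 0 < Ns < gm.n_samples:
        raise ValueError("Ns must split the combined data into two nonempty parts")
    Y = gm.K @ sm.W
    return ProjectedData(Ys=Y[:Ns], Yt=Y[Ns:])


def knn_predict(pd: ProjectedData, ys: np.ndarray, k: int = 5) -> np.ndarray:
    """Classify each projected target point by k-nearest source neighbors.

    Parameters
    ----------
    pd
        Projected coordinates.
    ys
        Source labels (length Ns).
    k
        Number of neighbors, 1 ≤ k ≤ Ns.

    Returns
    -------
    Length-Nt label vector.
    """
    ys = np.asarray(ys)
    Ns = pd.Ys.shape[0]
    if len(ys) != Ns:
        raise ValueError(f"labels have length {len(ys)}, expected {Ns}")
    if not 1 <= k <= Ns:
        raise ValueError(f"k={k} out of range 1..{Ns}")

    nn = NearestNeighbors(n_neighbors=k).fit(pd.Ys)
    _, idx = nn.kneighbors(pd.Yt)  # neighbors sorted by distance
    preds = np.empty(pd.Yt.shape[0], dtype=ys.dtype)
    for t in range(idx.shape[0]):
        neigh_labels = ys[idx[t]]
        values, counts = np.unique(neigh_labels, return_counts=True)
        tied = values[counts == counts.max()]
        if len(tied) == 1:
            preds[t] = tied[0]
        else:
            # nearest neighbor among tied classes wins
            for lab in neigh_labels:
                if lab in tied:
                    preds[t] = lab
                    break
    return preds
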
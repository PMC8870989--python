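"""Distribution diagnostics: center distance, total variance, MMD².

``report`` summarizes two point clouds by the Euclidean distance between
their centroids D(S,T), the total variance of each cloud (trace of the
population covariance, 1/n normalization), and the squared MMD.  For
point clouds these coincide: MMD² is exactly the squared distance
between the empirical means, so mmd2 = D(S,T)² holds identically — in
the learned subspace this is the quantity the solvers minimize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistributionReport", "report"]


@dataclass
class DistributionReport:
    D_ST: float
    Var_S: float
    Var_T: float
    mmd2: float
    space_tag: str = "original"

    def __str__(self) -> str:
        return (
            f"[{self.space_tag:>9}]  D(S,T) = {self.D_ST:.6g}   "
            f"Var(S) = {self.Var_S:.6g}   Var(T) = {self.Var_T:.6g}   "
            f"MMD^2 = {self.mmd2:.6g}"
        )


def _total_variance(X: np.ndarray) -> float:
    # trace of the population covariance = mean squared distance to the centroid
    return float(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))


def report(points_s: np.ndarray, points_t: np.ndarray, space_tag: str = "original") -> DistributionReport:
    """Distribution summary of a source and a target point cloud.

    Both inputs are samples-as-rows arrays of equal feature dimension.
    """
    S = np.atleast_2d(np.asarray(points_s, dtype=float))
    T = np.atleast_2d(np.asarray(points_t, dtype=float))
    if S.shape[0] == 0 or T.shape[0] == 0:
        raise ValueError("point sets must be nonempty")
    if S.shape[1] != T.shape[1]:
        raise ValueError("point sets must share feature dimension")
    delta = S.mean(axis=0) - T.mean(axis=0)
    d = float(np.linalg.norm(delta))
    return DistributionReport(
        D_ST=d,
        Var_S=_total_variance(S),
        Var_T=_total_variance(T),
        mmd2=d * d,
        space_tag=space_tag,
    )
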
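"""Source/target data bundles and delimited-text I/O.

The operators assume a fixed ordering of the combined sample matrix:
the Ns labeled source rows come first, the Nt unlabeled target rows
follow.  Labels are remapped internally to contiguous integers 1..C
(order of first appearance) so the scatter operators can index classes
densely; the original label values are kept for restoring predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DomainBundle", "combine", "read_matrix", "read_labels", "write_labels"]


@dataclass
class DomainBundle:
    """Combined source+target data with source labels.

    ``X`` stacks source rows (first ``Ns``) over target rows; ``ys`` are
    the remapped contiguous labels in 1..C and ``class_values`` maps a
    remapped label c back to ``class_values[c - 1]``.
    """

    X: np.ndarray
    ys: np.ndarray
    Ns: int
    Nt: int
    class_values: np.ndarray

    @property
    def N(self) -> int:
        return self.Ns + self.Nt

    @property
    def n_classes(self) -> int:
        return len(self.class_values)

    @property
    def Xs(self) -> np.ndarray:
        return self.X[: self.Ns]

    @property
    def Xt(self) -> np.ndarray:
        return self.X[self.Ns :]

    def original_labels(self, labels: np.ndarray) -> np.ndarray:
        """Map contiguous labels 1..C back to the user's label values."""
        return self.class_values[np.asarray(labels, dtype=int) - 1]


def combine(Xs: np.ndarray, ys: np.ndarray, Xt: np.ndarray) -> DomainBundle:
    """Stack source over target and remap labels to contiguous 1..C.

    Raises on feature-dimension mismatch, an empty domain, non-finite
    values, or a label vector of the wrong length.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    ys = np.asarray(ys).ravel()
    if Xs.shape[0] == 0 or Xt.shape[0] == 0:
        raise ValueError("both domains must be nonempty")
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: source has {Xs.shape[1]}, target has {Xt.shape[1]}"
        )
    if len(ys) != Xs.shape[0]:
        raise ValueError(f"labels have length {len(ys)}, expected {Xs.shape[0]}")
    if not (np.all(np.isfinite(Xs)) and np.all(np.isfinite(Xt))):
        raise ValueError("non-finite entries in input data")

    class_values, remapped = np.unique(ys, return_inverse=True)
    # np.unique sorts; reorder to first appearance so the remap is stable
    first_pos = np.array([np.argmax(remapped == c) for c in range(len(class_values))])
    order = np.argsort(first_pos, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    ys_contig = rank[remapped] + 1
    class_values = class_values[order]

    return DomainBundle(
        X=np.vstack([Xs, Xt]),
        ys=ys_contig.astype(int),
        Ns=Xs.shape[0],
        Nt=Xt.shape[0],
        class_values=class_values,
    )


def read_matrix(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a samples-as-rows numeric matrix from delimited text."""
    df = pd.read_csv(path, delimiter=delimiter, header=0 if header else None)
    return df.to_numpy(dtype=float)


def read_labels(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a single-column integer label vector."""
    df = pd.read_csv(path, delimiter=delimiter, header=0 if header else None)
    if df.shape[1] != 1:
        raise ValueError(f"label file must have one column, found {df.shape[1]}")
    return df.iloc[:, 0].to_numpy(dtype=int)


def write_labels(path, labels: np.ndarray) -> None:
    """Write predicted labels as a single-column CSV, one row per target sample."""
    pd.DataFrame({"label": np.asarray(labels).ravel()}).to_csv(path, index=False, header=False)
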
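"""High-level fit/predict workflow tying the stages together.

``fit`` dispatches on a method name:

* ``rkhsda``             — pure MMD objective (λ = 0) under the WᵀKW = I constraint
* ``slda_rkhsda``        — MMD + λ(Φ−Ψ) + μI, dense solver
* ``slda_rkhsda_sparse`` — MMD + γ(Φ−Ψ) + μI + λ‖W‖₂,₁, reweighted solver
* ``tca``                — TCA under the WᵀKHKW = I constraint
* ``tca_slda``           — TCA objective augmented with λ(Φ−Ψ)

``predict`` projects source and target through the fitted subspace and
runs the KNN classifier; ``evaluate`` adds accuracy and the original-
vs-subspace distribution diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .baselines import augment_with_slda, solve_tca
from .classify import ProjectedData, knn_predict, project
from .diagnostics import report
from .domain_data import DomainBundle
from .kernels import GramModel, KernelSpec, compute_gram
from .operators import OperatorSet, build_operator_set
from .solver_dense import SolverConfig, SubspaceModel, assemble_N, solve_subspace
from .solver_sparse import solve_sparse_subspace

METHODS = ("rkhsda", "slda_rkhsda", "slda_rkhsda_sparse", "tca", "tca_slda")

__all__ = ["FitResult", "METHODS", "fit", "predict", "evaluate", "raw_knn_accuracy"]


@dataclass
class FitResult:
    """Everything needed to project and classify after fitting."""

    method: str
    bundle: DomainBundle
    gram: GramModel
    operators: OperatorSet
    subspace: SubspaceModel
    config: SolverConfig


def fit(
    bundle: DomainBundle,
    method: str = "slda_rkhsda",
    kernel: KernelSpec | None = None,
    config: SolverConfig | None = None,
) -> FitResult:
    """Learn the subspace coefficients for the requested method."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    cfg = config if config is not None else SolverConfig()
    gm = compute_gram(bundle.X, kernel)
    ops = build_operator_set(gm, bundle.ys, bundle.Ns, bundle.Nt)

    if method == "rkhsda":
        sm = solve_subspace(gm, assemble_N(ops, replace(cfg, lam=0.0)), cfg.d)
    elif method == "slda_rkhsda":
        sm = solve_subspace(gm, assemble_N(ops, cfg), cfg.d)
    elif method == "slda_rkhsda_sparse":
        sm, _ = solve_sparse_subspace(gm, ops, cfg)
    elif method == "tca":
        sm = solve_tca(gm, bundle.Ns, bundle.Nt, cfg.mu, cfg.d)
    else:  # tca_slda
        extra = augment_with_slda(np.zeros((bundle.N, bundle.N)), ops, cfg.lam)
        sm = solve_tca(gm, bundle.Ns, bundle.Nt, cfg.mu, cfg.d, extra_quadratic=extra)

    return FitResult(method=method, bundle=bundle, gram=gm, operators=ops, subspace=sm, config=cfg)


def predict(fr: FitResult, k: int = 5) -> np.ndarray:
    """KNN-classify the target samples; labels are on the user's scale."""
    pd_ = project(fr.gram, fr.subspace, fr.bundle.Ns)
    preds = knn_predict(pd_, fr.bundle.ys, k=k)
    return fr.bundle.original_labels(preds)


def projected(fr: FitResult) -> ProjectedData:
    return project(fr.gram, fr.subspace, fr.bundle.Ns)


def raw_knn_accuracy(bundle: DomainBundle, yt_true: np.ndarray, k: int = 5) -> float:
    """Accuracy of KNN applied in the original feature space (no adaptation)."""
    pd_ = ProjectedData(Ys=bundle.Xs, Yt=bundle.Xt)
    preds = bundle.original_labels(knn_predict(pd_, bundle.ys, k=k))
    return float(np.mean(preds == np.asarray(yt_true)))


def evaluate(fr: FitResult, yt_true: np.ndarray, k: int = 5) -> dict:
    """Accuracy plus distribution diagnostics in both spaces."""
    preds = predict(fr, k=k)
    pd_ = projected(fr)
    rep_orig = report(fr.bundle.Xs, fr.bundle.Xt, space_tag="original")
    rep_sub = report(pd_.Ys, pd_.Yt, space_tag="subspace")
    return {
        "accuracy": float(np.mean(preds == np.asarray(yt_true))),
        "predictions": preds,
        "report_original": rep_orig,
        "report_subspace": rep_sub,
    }
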
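# rkhsda — kernel-subspace domain adaptation with a source-LDA regularizer

`rkhsda` is a Python library for unsupervised domain adaptation by
subspace learning in a reproducing-kernel Hilbert space (RKHS), aimed at
problems like cross-session EEG motor-imagery classification, where a
model trained on one recording day must classify data from another day
whose distribution has drifted.

## The model

Given labeled source samples X_s (N_s of them) and unlabeled target
samples X_t (N_t), form the combined set X = [X_s; X_t] and its Gram
matrix K (linear or RBF kernel). A d-dimensional subspace of the RKHS is
parameterized by a coefficient matrix W ∈ R^{N×d} over the kernel
sections; the projection of sample i is y_i = Wᵀ K_i (the i-th kernel
column). W is learned by

    min_W  tr(WᵀLW) + λ·tr(Wᵀ(Φ−Ψ)W) + μ·tr(WᵀW)   s.t.  WᵀKW = I_d

where

* **L = a aᵀ** with a = mean source kernel column − mean target kernel
  column, so tr(WᵀLW) is the squared maximum mean discrepancy (MMD)
  between the projected domain means;
* **Φ, Ψ** are within-/between-class scatter operators built from the
  source kernel columns, so λ·tr(Wᵀ(Φ−Ψ)W) compacts each projected
  source class while spreading class centers apart (the "source LDA"
  regularizer — the target is unlabeled, so only source labels enter);
* μ·tr(WᵀW) is a ridge term.

Writing K = UΣUᵀ, the constrained problem whitens to an ordinary
symmetric eigenproblem for M = Σ^{-1/2}Uᵀ(L+λ(Φ−Ψ)+μI)UΣ^{-1/2}; the d
eigenvectors with **smallest** eigenvalues give W = UΣ^{-1/2}V.

A row-sparse variant replaces the search over all kernel columns with
an L2,1 penalty λ‖W‖₂,₁ = λ·Σᵢ‖Wᵢ‖₂, solved by iteratively reweighted
generalized eigenproblems (L+γ(Φ−Ψ)+μI+λG)w = ηKw, where G is the
diagonal subgradient of the L2,1 norm, G_ii = 1/(2‖Wᵢ‖). Target samples
are then classified by KNN against the projected source samples.

Also included: a TCA baseline (same MMD objective under the
centered-kernel constraint WᵀKHKW = I), a generic "+SLDA" augmentation
hook for baselines, distribution diagnostics (center distance, total
variance, MMD²), seeded synthetic generators (domain-shifted Gaussian
mixtures; toy band-limited EEG), and an EEG preprocessing stage
(zero-phase Butterworth 8–30 Hz, epoch crop, log band-power features).

## Worked example

```bash
python examples/covariate_shift_adaptation.py
```

```
90 source / 90 target samples, 3 classes
raw-space KNN accuracy: 0.844

rkhsda: accuracy = 0.867
[ original]  D(S,T) = 3.49558   Var(S) = 15.1685   Var(T) = 16.7239   MMD^2 = 12.2191
[ subspace]  D(S,T) = 0.00193097   Var(S) = 0.112627   Var(T) = 0.106394   MMD^2 = 3.72863e-06

slda_rkhsda: accuracy = 0.878
[ original]  D(S,T) = 3.49558   Var(S) = 15.1685   Var(T) = 16.7239   MMD^2 = 12.2191
[ subspace]  D(S,T) = 0.00172463   Var(S) = 0.115294   Var(T) = 0.102635   MMD^2 = 2.97435e-06
```

Three Gaussian classes are rotated 30° and shifted in the target
domain. Raw-space KNN reaches 0.844; after learning the subspace, the
domain centers nearly coincide (D(S,T) drops from 3.50 to ~0.002, and
MMD² — identically D(S,T)² in the subspace — collapses), and target
accuracy rises, with the scatter regularizer adding a further margin.
The other examples (`sparse_subspace.py`, `tca_baseline_with_slda.py`,
`eeg_session_transfer.py`) demonstrate row-sparsity, the baseline
comparison, and the EEG pipeline, respectively.

## Command line

A thin CLI wraps the same workflow:

```bash
rkhsda simulate --out-dir data --seed 1
rkhsda fit --source data/source.csv --labels data/source_labels.csv \
           --target data/target.csv --method slda_rkhsda --dim 2 --out model
rkhsda predict --model model --out predictions.csv
rkhsda eval --model model --truth data/target_labels.csv
```

Options may also come from a YAML config (`--config`); explicit flags
win. Every run writes a manifest sufficient to re-run bit-identically.

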
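# Methods

## Model and assumptions

The package learns a finite-dimensional subspace of the RKHS generated
by a reproducing kernel k on the combined source+target sample set.
With K the N×N Gram matrix, a subspace basis θ_j = Σ_i W_ij k(·, x_i)
is orthonormal in the RKHS inner product exactly when WᵀKW = I_d, and
the coordinates of sample i in that basis are y_i = WᵀK_i (K_i the i-th
kernel column). Everything downstream — the MMD between projected
domain means, the LDA-style scatters of the projected source classes —
is therefore a quadratic form tr(WᵀAW) in one of three N×N PSD
operators built from kernel columns:

* MMD operator `L = a aᵀ`, a = mean source column − mean target column
  (rank ≤ 1, so a d ≤ N−1 dimensional subspace can annihilate it);
* within-class scatter `Φ = (1/N_s) Σ_c Σ_{i∈c} (K_i − m_c)(K_i − m_c)ᵀ`;
* between-class scatter `Ψ = Σ_c (N_c/N_s)(m_c − m)(m_c − m)ᵀ`,

with m_c the mean source column of class c and m the mean over all N_s
source columns. The grand center m uses the 1/N_s normalization: the
regularizer sees only labeled source data, and 1/N_s is the choice
under which the LDA identity Σ_c (N_c/N_s) m_c = m holds, making
tr(WᵀΨW) the standard between-class scatter of the projected source
points. Both scatter operators keep the full length-N columns, so they
are conformable with L even though only source columns enter.

The working assumption is classic covariate shift: the class structure
of the source survives projection, and pulling the projected domain
means together makes source neighbors informative for target points.
MMD here is a first-moment criterion; the scatter term compensates by
shaping the source geometry, and nothing in the model aligns
higher-order moments of the target.

## Solvers

**Dense.** min tr(WᵀNW) s.t. WᵀKW = I_d, N = L + λ(Φ−Ψ) + μI. K is
eigendecomposed once (K = UΣUᵀ); substituting V = Σ^{1/2}UᵀW turns the
problem into an unconstrained symmetric eigenproblem for
M = Σ^{-1/2}UᵀNUΣ^{-1/2}, minimized by the d smallest eigenpairs;
W = UΣ^{-1/2}V and the achieved objective is the eigenvalue sum. Since
Φ−Ψ can make N indefinite, negative eigenvalues of M are legitimate
and are selected first. Degenerate eigenvalues make W unique only up to
rotation of the eigenspace; all subspace comparisons in the tests use
principal angles, and output is made reproducible by fixing each
eigenvector's sign (largest-magnitude entry positive).

**Numerical rank.** Real Gram matrices are routinely singular
(duplicate samples, linear kernel with N > D). A diagonal jitter of
1e-10·trace(K)/N is added whenever the smallest eigenvalue falls below
that amount, and the whitening uses only eigendirections above ten
times the jitter: directions the jitter itself manufactured carry no
kernel mass, would enter the objective at near-zero cost, and would
produce meaningless coordinates. The effective search dimension is
therefore the numerical rank r, and d ≤ r is enforced.

**Sparse.** The L2,1 penalty λΣ‖W_row‖ is handled by the standard
reweighted scheme: iterate the eigenproblem with N replaced by
N + λG, where G = diag(1/(2‖W_i‖)) is the subgradient of the penalty at
the previous iterate, until the relative change of the true objective
drops below `tol` (default 1e-6) or `max_iter` (default 30). Each
iterate is exactly K-orthonormal because it comes from the same
whitening route. Inside the iteration the subgradient is evaluated as
G_ii = 1/(2·max(‖W_i‖, ε)) with ε = 1e-8·max row norm: with a hard zero
on vanishing rows (the nominal subgradient), a row that crosses the
threshold loses its penalty entirely and the objective can jump;
the capped form keeps the surrogate a majorizer up to O(ε) and the
descent monotone, which the tests verify on randomized problems. The
tail of the iteration can be slow when many rows decay simultaneously;
with the default tolerance, convergence on the bundled problem sizes
takes tens of iterations.

**TCA baseline.** Same objective family under the centered-kernel
constraint WᵀKHKW = I_d, H = I − (1/N)11ᵀ. The MMD term is written in
the coefficient convention L_coef = e eᵀ (e_i = 1/N_s or −1/N_t);
K L_coef K = (Ke)(Ke)ᵀ coincides with the column-convention operator
above, so the solver whitens KHK (rank ≤ N−1; jittered the same way)
and reuses the dense machinery. `augment_with_slda` adds λ(Φ−Ψ) to any
baseline quadratic, under either constraint style.

**Classification.** Euclidean KNN in the subspace (the kernel geometry
is already encoded by the projection), k = 5 by default. Vote ties go
to the class of the single nearest neighbor among the tied classes —
deterministic given input order.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| kernel | linear or RBF | RBF | nonlinear shift needs a nonlinear feature map |
| bandwidth σ | RBF scale | median pairwise distance | standard heuristic; no principled value is known a priori |
| d | subspace dimension | 2 | small problems; accuracy is flat in d on the bundled generators |
| λ | scatter weight (dense) | 1.0 (pipeline runs use 0.1) | order-of-magnitude balance against the MMD term |
| μ | ridge | 0.1 | regularizes the indefinite objective |
| γ | scatter weight (sparse) | 0.01 | the companion weight used for the sparse variant |
| λ_sparse | L2,1 weight | 0.1 | visible row sparsity without collapsing accuracy |
| tol / max_iter | sparse stopping | 1e-6 / 30 | relative-change criterion |
| k (KNN) | neighbors | 5 | robust majority vote at ~30 samples/class |

## Synthetic study conditions

`ShiftScenario` (defaults: C = 3 classes, D = 10 features, 30 samples
per class per domain, class means spaced 3·σ_noise along the first
axis, target rotated 30° in the first two coordinates and translated
2·σ_noise along the second, unit noise) produces a class-structured
covariate shift that plain KNN partially survives but a kernel subspace
can largely remove — the regime the method is designed for. The
rotation acts only in a 2-plane to keep the shift interpretable and
partially correctable by a linear-in-RKHS map. Ground-truth target
labels are returned beside the bundle and are accepted by no fitting
interface.

`ToyEEGScenario` (6 channels, 250 Hz, 7 s trials, 15 trials/class,
class oscillations at 10 and 22 Hz with distinct deterministic spatial
patterns, unit-SD noise, snr = 1) emulates the band-limited,
spatially-patterned structure of motor-imagery rhythms; the target
session re-draws the noise and applies per-channel gain drift
(SD 0.2). It is not a forward model: no volume conduction, artifacts,
non-stationarity within a session, or realistic spectra. Passing tests
therefore demonstrate the pipeline's mechanics and its behavior under
idealized session drift, not clinical-grade performance.

The EEG stage band-passes 8–30 Hz with an order-5 Butterworth filter
applied forward-backward (zero phase; effective order doubles), crops
the half-open window [1.5 s, 6.5 s) — exactly 1250 samples per channel
at 250 Hz — and reduces each channel to log band-power (variance of the
filtered epoch, log-transformed). A flatten mode keeps the raw cropped
samples for experimentation. Log band-power is the default because it
is the minimal feature that motor-imagery rhythms support; richer maps
(CSP and friends) are out of scope.

## Numerical choices and edge cases

* Diagnostics use population (1/n) normalization for the total
  variance (trace of the covariance); recorded in the report metadata.
  In the subspace, D(S,T)² equals the quadratic-form MMD² identically.
* Labels are remapped to contiguous 1..C by first appearance and
  restored on output; duplicate rows across domains are allowed.
* `solve_subspace` rejects objective matrices asymmetric beyond
  1e-8 relative, and requests for d above the numerical rank.
* All randomness flows from explicit integer seeds; generators are
  bit-reproducible for a fixed seed.

## Problem sizes

Bundled tests and the reproduction script run at desk scale: N ≤ 180
samples for the shift benchmarks (20 seeds per estimate), 30 trials per
EEG session. These sizes give stable means (standard errors on
accuracies ≈ 0.01) while the full suite runs in seconds.

## Known limitations

* The MMD term matches means only; strongly nonlinear or
  higher-moment shifts are out of the model's reach even in the RKHS.
* The sparse iteration is a local scheme; different λ_sparse paths can
  reach different row supports on near-degenerate problems.
* No multi-source adaptation, class-conditional MMD, or classifier
  beyond KNN; GDF/recording-file parsing is out of scope (convert to
  per-trial CSV externally).
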
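# Methods

## Model

`tsmdl` fits a shared multi-layer dictionary factorization to two labeled
domains at once.  Layer `l` approximates its input — the data matrix `X =
[X_s, X_t]` at layer 1, the previous layer's codes thereafter — as `Z_{l−1}
≈ D_l Z_l`, with every dictionary column constrained to unit Euclidean
norm (removing the scale ambiguity between atoms and codes).  Three
penalties act on each layer's codes:

* a ridge term `λ_l‖Z_l‖_F²` (the codes are dense, not sparse; there is no
  ℓ0/ℓ1 term anywhere in the model),
* supervised graph terms `α_l Tr(Z_l P^C Z_lᵀ) − β_l Tr(Z_l P^M Z_lᵀ)`
  pulling same-class codes together and pushing different-class codes
  apart, and
* on the deepest layer only, a classification term `λ Σ_c f(Z_L, y_c,
  w_c, b_c)` coupling the codes to one-vs-rest linear max-margin
  classifiers.

### Graphs

Pair weights connect ordered pairs of samples *within a domain*: entry
`(i, j)` of the same-class matrix is `1/|C|` when `y_i = y_j`, `i ≠ j`,
where `|C|` is the total count of ordered same-class pairs in that
domain's graph; the different-class matrix uses `1/|M|` likewise.  This
normalization makes each weight matrix's entries sum to one, so the pull
and push terms stay scale-comparable regardless of sample count or class
balance.  Self-pairs are excluded: they contribute nothing to the
penalty and would only dilute the normalization.  Laplacians are
`P = degree(Q) − Q`; per-domain Laplacians are joined block-diagonally
(source block first), so no cross-domain edge ever exists — the domains
communicate only through the shared dictionaries.  The pairwise form
`Σ_ij Q_ij‖z_i − z_j‖²` equals `2 Tr(Z P Zᵀ)`; the trace form is
canonical throughout the implementation and the pairwise double loop is
kept only as a test oracle (with the factor 2 applied).

Because labels never change during a fit, the graphs are
iteration-invariant; they are computed once, with recomputation per
iteration available behind `recompute_graphs=True` for fidelity to the
alternating scheme as usually written.

### Alternating optimization

All updates descend on a single surrogate objective (see *Classifier*
below for what "surrogate" means here):

1. **Dictionaries.** Column-wise block coordinate descent on
   `‖input − D Z‖_F²` with codes fixed: the exact constrained minimizer of
   atom `j` given the others is `E_j z_jᵀ` normalized, where `E_j` is the
   residual excluding atom `j`.  Ten sweeps or relative improvement below
   1e−6.  An atom whose code row is all zero is kept unchanged (logged).
   Codes are *not* rescaled here — the dictionary step is defined purely
   as the constrained minimization over `D`.
2. **Inner-layer codes.** The stationarity condition of the layer
   objective is the two-sided linear equation
   `(D_lᵀD_l + δI) Z + Z M = D_lᵀ Z_{l−1} + D_{l+1}Z_{l+1}` with
   `M = α_l P^C − β_l P^M + λ_l I` and `δ = 1` exactly when a next layer
   exists (the `+I` comes from the next layer's reconstruction term; it is
   absent at the last layer).  Both coefficient matrices are symmetric, so
   the equation is solved exactly by eigendecomposition:
   `Z = U_A [ (U_AᵀBV_M) ⊘ (λ_A,i + λ_M,j) ] V_Mᵀ`.  The solve requires
   `min eig(A) + min eig(M) > 0`; a violation (β too large relative to λ)
   raises `ill-posed hyperparameters` rather than returning a saddle
   point.  With `β_l = 0` and `λ_l > 0` the system is always positive
   definite.
3. **Last-layer codes.** Per-column block coordinate descent.  The
   classification term is handled by an active-set squared-hinge
   surrogate: classes currently violating the margin
   (`y_c(w_cᵀz_i + b_c) < 1`) contribute `(1 − y_c(w_cᵀz_i + b_c))²` and
   enter the per-column linear system through `λ Σ_c w_c w_cᵀ`.  Because
   the active set is frozen during each solve, the candidate column can in
   principle overshoot on the true piecewise-quadratic function, so each
   candidate is accepted only if it lowers the exact per-column value —
   the update is therefore guaranteed non-increasing.  Sweeps repeat until
   the active sets stabilize, at most 5.
4. **Classifier.** Per class, with targets `±1`, the squared-hinge
   (L2-loss) SVM objective `‖w‖²/(2·cost) + Σ_i max(0, 1 − y_i(wᵀz_i +
   b))²` is minimized by L-BFGS, warm-started from the previous
   parameters.  The squared-hinge loss was chosen over the plain hinge as
   the package's design choice so that the classifier refit, the
   last-layer code update, and the logged objective all share *one*
   function: L-BFGS started at the previous optimum cannot increase it,
   which is what makes the training log provably non-increasing.  A
   hand-rolled solver is used rather than liblinear because liblinear
   regularizes the intercept, which would break the exact correspondence
   between the refit and the logged objective (sklearn's `LinearSVC`
   appears in the test suite as an independent cross-check).  The hinge
   loss remains available in `total_objective(loss="hinge")` for
   reporting.

The logged **surrogate objective** is the full model objective with the
squared-hinge classification loss and the classifiers' ridge terms
`‖w_c‖²/(2·cost)` included inside the `λ` factor.  Every step above
minimizes its own block of exactly this function, so the log is
non-increasing up to floating-point error (asserted at relative slack
1e−8).

A single classifier is trained on the concatenated source + target codes
— the two domains' classification sums merge once the matrices are
concatenated, and a separate target classifier would see too few labels
to be the point of transfer.

### Initialization

Dictionaries are initialized by plain K-SVD (reconstruction + ℓ0 sparsity
`T`, default 3, 10 iterations) run separately per class on that layer's
input, with `⌊K_l/C⌋` atoms per class and remainder atoms assigned to the
largest class; dead atoms are replaced by the worst-represented sample,
keeping the run deterministic given the seed.  Codes are initialized by
the ridge encoder `(D_lᵀD_l + λ_l I)⁻¹D_lᵀ` applied to the layer input —
coherent with the K-SVD dictionaries, whereas a PCA projection would
ignore them (both initializations only seed the first dictionary update;
the choice is not critical).  SVM parameters are fitted once on the
initial codes before the first outer iteration so the surrogate objective
is well defined from iteration 0.

### Prediction

`Θ_l = (D_lᵀD_l + λ_l I)⁻¹D_lᵀ` applied layer by layer,
`z = Θ_L(…(Θ_1 x))`, then `argmax_c w_cᵀz + b_c` with ties broken toward
the lowest class index (classes are indexed in sorted label order, so
prediction is deterministic).  The graph terms cannot appear in the
encoder — they couple training samples to each other and have no meaning
for a single unseen sample — so the test-time encoder is the model's
inductive ridge approximation.  `λ_l = 0` with a rank-deficient
dictionary raises with a suggestion to set `λ_l > 0`; internally a floor
of 1e−8 is used when a layer's ridge weight is exactly zero.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `n_layers` L | depth of the stack | 3 | supported 1–5 |
| `dict_sizes` K_l | atoms per layer | (500, 450, 400, 350, 300) truncated to L | the convention for full-size image tasks; desk-scale tasks use smaller values |
| `alpha` α_l | same-class pull weight | 0.1 | from the conventional grid {0.01, 0.05, 0.1, …, 2} |
| `beta` β_l | different-class push weight | 0.01 | must stay small enough that `λ_l I − β_l P^M` keeps the system PD; checked at solve time |
| `lam` λ_l | ridge weight on codes | 0.1 | also the encoder ridge |
| `clf_weight` λ | classifier coupling | 0.1 | 0 decouples the classifier entirely |
| `svm_cost` | SVM trade-off C | 1.0 | exposed, rarely moved |
| `max_outer_iters` / `rel_tol` | convergence control | 30 / 1e−5 | relative change of the surrogate objective |
| `ksvd_sparsity` T / `ksvd_iters` | init only | 3 / 10 | |

All randomness (K-SVD column selection, atom respawns) flows from the
single integer `seed`.

## Feature extraction

The texture front end produces a fixed 540-length vector per grayscale
image (minimum 32 × 32):

* **40 wavelet features** — 3-level `db4` decomposition → 10 subbands;
  per subband: coefficient mean, standard deviation, energy (sum of
  squares), and energy entropy (Shannon entropy of the normalized squared
  coefficients).
* **500 GLCM features** — gray-level co-occurrence matrices (symmetric,
  normalized) for 5 distances {1…5} × 4 angles {0°, 45°, 90°, 135°}, each
  at 5 quantization settings {8, 16, 32, 64, 128 levels} (equal-width
  binning of the observed intensity range), each contributing contrast,
  correlation, energy, homogeneity, and entropy: 5 × 4 × 5 × 5 = 500.

The 40 + 500 split is this package's documented convention; the total
length is the conformance target, and any alternative composition is
expressible through `FeatureConfig`.  GLCM correlation is undefined on a
zero-variance image and is emitted as 0 (logged) so vectors stay finite.
An optional training-set standardization (zero mean, unit variance;
zero-variance features left unscaled) is provided separately from
extraction.

## Synthetic data

`generate_transfer_task` draws data from the model's own generative
assumption: random unit-norm dictionaries shared across layers,
deepest-layer codes = class prototype + isotropic unit-variance noise
(prototypes are mutually orthogonal directions scaled so every pair of
classes sits `class_separation` within-class standard deviations apart),
observations = multi-layer reconstruction + Gaussian noise `noise_sd`,
exactly balanced classes per domain.  Domain shift perturbs the *target
dictionaries* (`D + shift·G`, columns renormalized): the model's premise
is a shared dictionary, and this knob violates that premise smoothly —
0 is ideal transfer, large values create a negative-transfer regime.

What the generator does **not** emulate: real image statistics, class
imbalance, label noise, non-Gaussian heteroscedastic noise, or mean-shift
/ covariate-shift mechanisms.  Tests passing on these fixtures show the
optimizer and the transfer mechanism behave as designed under the model's
own assumptions, not that the model fits any particular real dataset.

Dense isotropic codes leave a dictionary identifiable only up to rotation
(`DZ = (DR)(RᵀZ)` with the ridge and graph terms rotation-invariant in
code space), so atom-recovery claims cannot be tested on that generator
in principle.  `generate_sparse_recovery_task` therefore produces the
classic identifiable setting — each sample activates exactly one atom
from its class's disjoint support, coefficient magnitude uniform in
[1, 2] with random sign — on which best-assignment |cosine| against the
true atoms is meaningful.

## Problem sizes used in the checks

The repeated checks run at desk scale, chosen once: monotonicity on ten
3-layer tasks (d = 32, K = (24, 16, 8), 120 + 120 samples); code-update
oracle equivalence on 50 random instances with K·N ≤ 200 (the dense
Kronecker system is O((KN)³)); dictionary recovery at d = 16, K = 8,
n = 400, 4 classes, noiseless; the transfer comparison on ten seeds of a
d = 32, two-layer (K = 16, 8) task with 200 + 200 samples,
`domain_shift = 0.2`, `class_separation = 2`, `noise_sd = 0.5`, training
on the full source plus a stratified 10% of the target (20 samples —
small enough that labels are genuinely scarce, large enough that the
target-only baseline can fit its K = 16 first layer).  The 10% target
split is stratified by class so both training conditions see every class.

## Numerical choices and degenerate inputs

* PD checks use a 1e−10 floor on `min eig(A) + min eig(M)`.
* Unit-norm constraint enforced to 1e−8 after every update; K-SVD atom
  signs fixed deterministically (largest-magnitude entry positive).
* Zero-variance features and all-zero samples are accepted; an all-zero
  code row keeps its previous atom.
* Model archives: JSON manifest (written last, so an interrupted save is
  never loadable) + one `.npy` per matrix; round-trip exact to 1e−12;
  format version checked on load.  Feature tables are plain CSV/TSV with
  reserved `label` and `domain` columns; class labels are strings, and
  internal class indexing is the sorted order of unique labels.

## Limitations

* The surrogate (squared-hinge) classifier term differs from a plain
  hinge SVM; with few margin violations the two coincide in behavior, but
  reported objectives are not comparable across the two losses.
* The encoder drops the graph terms, so training codes and encoded codes
  of the same sample differ unless the graph weights are small or the fit
  is noiseless.
* Per-layer graphs are shared across layers (labels do not change with
  depth); the API accepts per-layer Laplacians so a layer-specific
  construction remains expressible.
* Hyperparameter search is left to the user (a simple loop over the
  conventional grid); nothing is automated beyond `run_experiment`.
* The optimization is alternating descent on a non-convex problem:
  monotone convergence to a stationary point, not a global optimum.
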
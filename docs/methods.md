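# Methods

## Model

A cohort of N images on a common H × W pixel grid is modeled as N
realizations of a square-integrable random function x(s, t) on the unit
square. The grid is mapped to pixel-center coordinates s_h = (h + ½)/H,
t_w = (w + ½)/W, so basis-size choices do not depend on resolution.

Each image is expanded in the tensor product of the L²[0,1]-orthonormal
trigonometric family (1, √2 sin 2πmt, √2 cos 2πmt, m = 1, 2, …), K functions
per axis. Coefficients are obtained by least squares on the pixel grid,
computed separably: with 1D design matrices Bs (H × K) and Bt (W × K), the
K × K coefficient block of image X solves (BsᵀBs) M (BtᵀBt) = Bsᵀ X Bt. On a
tensor grid this is algebraically identical to the joint least-squares fit
of all K² tensor functions, at O(HWK) instead of O(HWK⁴) cost. We fit by
least squares rather than by continuous inner products because images are
discrete; on uniform grids the two agree up to quadrature error, and for
band-limited signals (frequency below the grid Nyquist) exactly.

After column-centering the coefficient matrix C (equivalent to centering
the images, since the expansion is linear), the covariance operator of the
cohort is represented in coefficient space by the K² × K² matrix (1/N)CᵀC;
the 4-index covariance kernel is never materialized. The eigenproblem
(1/N)CᵀC b = λb yields eigenvalues λ_j and orthonormal coefficient vectors
b_j; eigenfunctions are β_j(s,t) = [φ(s) ⊗ φ(t)]ᵀ b_j and FPC scores are the
coefficient inner products ξ_ij = C_iᵀ b_j, which equal the L² projections
exactly because the tensor basis is orthonormal — no Gram correction is
needed, which is the reason this basis family was chosen.

A centered cohort of N images has at most min(N − 1, K²) nonzero
eigenvalues. A fully degenerate cohort (all images identical) yields all
λ_j = 0 and all-zero scores, which is returned as a valid result, not an
error.

## Randomized feature selection

The score matrix A (N samples × n score features) is reduced to r actual
columns. The selection needs an approximation Z to the top-k right singular
subspace of A; computing it from a Gaussian sketch (Y = AG, Q = orth(Y),
Z = top-k right singular vectors of QᵀA) avoids a full SVD of A. Columns
are then drawn i.i.d. with replacement with leverage probabilities
q_i = ‖Z_(i)‖²/‖Z‖²_F (which sum to one by construction, since ‖Z‖²_F = k),
and rescaled by S(t,t) = 1/√(r q_{i_t}). Duplicates are retained: the
rescaling makes (ΩS)(ΩS)ᵀ an unbiased estimator of the identity, and
deduplication would destroy that property.

The default feature count is r = k + ⌈k/ε⌉ + 1 with ε ∈ (0, 1] an allowed
clustering-error parameter (smaller ε ⇒ more features). The printed form of
this rule is typographically ambiguous in its source material; the adopted
reading is the one under which r decreases as the error allowance grows,
and a plain `r` override is exposed for users who want to bypass the
formula entirely.

One integer seed drives both stochastic stages, split as (seed) for the
Gaussian sketch and (seed + 1) for the categorical sampling so each stage
can be reproduced independently. Every stochastic operation in the package
is a pure function of (inputs, seed).

Numerical choices: Y is orthonormalized by Householder QR; columns whose R
diagonal falls below 1e-10 (relative) are dropped as rank-lost; a sketch
whose k-th singular value of QᵀA is below 1e-10 (relative) raises a
rank-deficiency error suggesting a different seed or smaller k.

## Clustering and evaluation

The k-means objective is used in its matrix form F(A, X) = ‖A − XXᵀA‖²_F
with the normalized indicator X (entries 1/√s_j), which equals the
within-cluster sum of squares; both forms are computed and cross-checked in
debug mode. The k-means driver is Lloyd's algorithm with k-means++
initialization and best-of-restarts (default 25, 300 iterations max),
provided by scikit-learn; the objective reported is always recomputed
through the indicator-matrix form. Spectral clustering is implemented
directly to a fixed recipe: Gaussian affinity with bandwidth equal to the
median pairwise distance, symmetric-normalized Laplacian, embedding in the
top-k eigenvectors with row normalization, then k-means on the embedded
rows; its objective is reported on the original features.

Accuracy against known labels is maximized over cluster-to-class
correspondences. For k ≤ 6 this is an exhaustive permutation search; beyond
that an optimal linear assignment on the confusion matrix is used, which is
exactly equivalent for this objective. This matching convention is a design
choice of the package — different conventions exist in the literature and
are not always stated. For k = 2, sensitivity and specificity are the
recalls of the designated positive and negative classes under the chosen
mapping; for k > 2 per-class recalls and the full matched confusion table
are reported.

The diagnostics module verifies the chain ‖A − A_k‖²_F ≤ F_opt ≤ F(X̃) for
any partition X̃: the left bound by exact truncated SVD, the middle by
exhaustive enumeration of all k-partitions, limited to m ≤ 12 samples
(Stirling-number growth makes larger m impractical and the bound is
size-independent in structure).

## Synthetic data

The generator defines cohorts in coefficient space: each group has a smooth
mean surface given by a K² coefficient vector; within-group variation is
carried by a small set of fixed orthonormal tensor-basis functions (by
default the diagonal functions φ₂φ₂, φ₃φ₃, …) with specified score standard
deviations; pixel noise is i.i.d. Gaussian. Because the components are
exactly orthonormal, the population eigenvalues of a single-group, zero-noise
cohort are exactly the squared score standard deviations and the population
eigenfunctions are the components themselves — an analytic ground truth
that real histology data cannot provide. Values are not clipped to [0, 1]
(clipping would break Gaussianity); the PNG writer clips when exporting to
8-bit files.

Gaussian pixel noise was chosen over Poisson or speckle models as the
simplest model consistent with the L² machinery; the generator consequently
does not emulate stain variation, texture, illumination gradients, or
spatially correlated noise. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated model, not robustness to
real histology artifacts.

The feature-matrix generator places k cluster centers in the first
n_informative coordinates, rescaled so the minimum pairwise center distance
equals `separation`, with unit within-cluster noise by default and
independent distractor features (default sd 1.0, configurable); labels are
balanced. separation ≈ 10 with unit noise is effectively noiseless for
k-means; separation 0 collapses the centers to chance-level clustering.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| K | 1D basis size (K² tensor functions) | 15 (pipeline) | resolves smooth structure at histology-thumbnail scales; requires K² ≤ HW |
| J | FPC components kept | smallest J with ≥ 95% variance explained | standard scree criterion; overridable |
| k | number of clusters | 2 | two-group designs (tumor/normal, sensitive/resistant) |
| ε | selection error allowance | 1/3 | gives r = k + 3k + 1, a small multiple of k |
| r | features selected | k + ⌈k/ε⌉ + 1 | see above; override available |
| restarts | k-means restarts | 25 | small-instance enumeration shows ≥ 95% optimality at 20 |
| noise_sd | generator pixel noise | 0.05 | a few percent of an 8-bit dynamic range |

## Problem sizes used in the verification suite

The test suite and the acceptance script run entirely on synthetic data at
sizes chosen to make every property checkable exactly or by enumeration:
random cohorts with N ≤ 20 and K ≤ 4 for eigensolver agreement; N = 500
32 × 32 images for parameter recovery (sampling error of a variance
estimate at N = 500 is ≈ 6%, inside the 15% band checked); 20,000
Monte-Carlo draws at n = 10, r = 5 for sampling unbiasedness (standard
error ≈ 0.01 per entry against a 0.05 band); m ≤ 12 for enumerated k-means
optima; a 100-image two-group cohort for the end-to-end pipeline; and 100
repetitions for selection stability.

## Known limitations

- All images in a run must share one pixel grid; no registration, tiling or
  multi-resolution support.
- RGB images are reduced to Rec. 709 luminance; color-aware FPCA is out of
  scope.
- The Fourier basis is periodic on [0,1]; images with strong boundary
  mismatch (left/right or top/bottom edges differing sharply) incur Gibbs
  effects that inflate high-frequency coefficients. B-spline or wavelet
  bases are not provided.
- Sampling is with replacement only; deterministic column-selection
  variants are not implemented.
- The clustering-error guarantee is verified empirically as a bound chain
  on small instances; no formal constant is certified at run time.
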
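# imgfpc

Unsupervised clustering of gridded image cohorts — e.g. histology tissue
images — via **two-dimensional functional principal component analysis
(FPCA)** for feature extraction and **randomized leverage-score feature
selection** with a provable k-means guarantee.

## Who this is for

Analysts with a cohort of equally sized grayscale (or RGB) images who want
to cluster samples into a small number of groups without labels, while
reducing tens of thousands of pixels to a handful of interpretable smooth
features. Everything is verifiable on synthetic cohorts generated by the
package itself.

## The method

**Feature extraction.** Each image is treated as a function x_i(s, t) on the
unit square and expanded in a tensor-product Fourier basis,

    x_i(s, t) = Σ_k Σ_l c_kl^(i) φ_k(s) φ_l(t),

with the L²[0,1]-orthonormal family φ₁ = 1, φ₂ = √2 sin 2πt, φ₃ = √2 cos 2πt, …
Stacking the coefficient rows into the N × K² matrix C, the covariance
operator of the centered cohort is represented by (1/N) CᵀC and the
functional eigenproblem reduces to the matrix eigenequation

    (1/N) CᵀC b = λ b.

Eigenfunctions are β_j(s, t) = [φ(s) ⊗ φ(t)]ᵀ b_j and the FPC score of image
i on component j is ξ_ij = ∫∫ x_i β_j = C_iᵀ b_j — exact in coefficient
space because the tensor basis is orthonormal.

**Feature selection.** The N × n score matrix A is reduced to r actual
columns by randomized column subset selection: a Gaussian sketch Y = AG is
orthonormalized into Q, Z holds the top-k right singular vectors of QᵀA,
and r indices are drawn i.i.d. with replacement with leverage probabilities
q_i = ‖Z_(i)‖² / ‖Z‖²_F. The selected matrix C = AΩS (S(t,t) = 1/√(r·q_{i_t}))
satisfies E[(ΩS)(ΩS)ᵀ] = I, and k-means on C approximately optimizes the
objective F(A, X) = ‖A − XXᵀA‖²_F on the full matrix. The default feature
count is r = k + ⌈k/ε⌉ + 1.

**Clustering and evaluation.** k-means (Lloyd + k-means++ restarts) or
normalized spectral clustering; accuracy / sensitivity / specificity under
optimal cluster-to-class label matching; exhaustive-partition diagnostics of
the bound chain ‖A − A_k‖²_F ≤ F_opt ≤ F(partition) for small cohorts; and a
repeated-seed stability analysis of the selected feature sets.

## Worked example

```python
import numpy as np
from imgfpc import (CohortSpec, FourierBasis, center_coefficients,
                    compute_scores, eigen_decompose, fit_coefficients,
                    generate_cohort)

K = 8
spec = CohortSpec(n_per_group=(200,), H=32, W=32, K=K,
                  group_mean_coeffs=(np.zeros(K * K),),
                  score_sds=(2.0, 1.0, 0.5), noise_sd=0.02, seed=0)
images, _ = generate_cohort(spec)
coef = center_coefficients(fit_coefficients(images, FourierBasis(K)))
es = eigen_decompose(coef, J=10)
print(np.round(es.eigenvalues[:5], 3))
```

prints

```
[4.249 0.899 0.238 0.    0.   ]
```

— the three leading eigenvalues estimate the generator's score variances
(2.0², 1.0², 0.5²) = (4, 1, 0.25) up to sampling error, and the remainder is
pixel noise. See `examples/` for narrative scripts covering reconstruction,
feature selection with the enumerated bound chain, the full PNG-to-report
pipeline, and selection stability; each prints the numbers it computes and
one line on what they mean.

## Command line

```bash
imgfpc simulate --groups 2 --n-per-group 20 --size 32 --out cohort/
imgfpc run --images cohort/ --k 2 --epsilon 0.333 --basis-k 8 \
           --truth cohort/truth.csv --out results/
imgfpc stability --features results/scores.csv --truth cohort/truth.csv --k 2
```

`imgfpc run` writes `scores.csv`, `fpca.json`, `selection_plan.json`,
`assignments.csv`, `report.json` and `run_log.json`; identical config and
seed reproduce identical artifacts byte for byte.

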
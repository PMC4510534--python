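"""Leverage-score column selection on a feature matrix with two signal columns.

Demonstrates that the sampling probabilities concentrate on the columns
spanning the top-k singular subspace, and that the selected, rescaled matrix
preserves the k-means geometry (bound chain checked by enumeration).
"""

import numpy as np

from imgfpc import (
    FeatureMatrix, number_of_features, run_kmeans, select_features,
    selection_error_diagnostics,
)

rng = np.random.default_rng(3)
m, n = 10, 15
A = 0.05 * rng.standard_normal((m, n))
A[:, 4] += np.r_[np.zeros(5), 8 * np.ones(5)]   # cluster-separating column
A[:, 9] += 3 * rng.standard_normal(m)           # high-variance column
fm = FeatureMatrix(A)

k, eps = 2, 1 / 3
r = number_of_features(k, eps)
print(f"selecting r = {r} of {n} features (k = {k}, epsilon = {eps:.3f})")

C, plan, sketch = select_features(fm, k=k, epsilon=eps, seed=0)
print("sampling probabilities (rounded):", np.round(plan.q, 3))
print("selected feature indices:", sorted(plan.indices.tolist()))
# Nearly all probability mass sits on columns 4 and 9, the only columns with
# leverage on the top-2 right singular subspace; draws repeat them.

model = run_kmeans(C, k=k, seed=0)
d = selection_error_diagnostics(fm, model.assignment, k=k)
print(f"F (selected features, vs full A): {d.objective:.4f}")
print(f"enumerated optimum F_opt:         {d.brute_force_optimum:.4f}")
print(f"rank-k SVD lower bound:           {d.svd_lower_bound:.4f}")
print("bound chain holds:", d.chain_holds)
# The partition found on 5 selected columns attains (or nearly attains) the
# enumerated k-means optimum on the full 15-column matrix.
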
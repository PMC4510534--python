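"""Randomized leverage-score feature selection for k-means clustering.

Given an m x n data matrix A (samples x features, e.g. FPC scores), the
algorithm selects r actual columns whose k-means optimum provably tracks the
optimum on the full matrix:

1. draw an n x r standard Gaussian matrix G;
2. form the sketch Y = A G and orthonormalize it into Q;
3. take Z, the top-k right singular vectors of Q^T A — an approximation to
   the top-k right singular subspace of A;
4. sample r column indices i.i.d. with replacement with leverage
   probabilities q_i = ||Z_(i)||^2 / ||Z||_F^2;
5. return C = A Omega S, where Omega picks the sampled columns and the
   diagonal rescaling S(t,t) = 1 / sqrt(r q_{i_t}) makes
   E[(Omega S)(Omega S)^T] = I_n, preserving Frobenius-norm geometry in
   expectation.

The number of selected features defaults to r = k + ceil(k/eps) + 1, where
eps is the allowed clustering-error parameter (smaller eps selects more
features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .errors import (
    ContractViolationError,
    InvalidArgumentError,
    RankDeficiencyError,
    SizeLimitError,
)

__all__ = [
    "FeatureMatrix",
    "SketchResult",
    "SamplingPlan",
    "number_of_features",
    "sketch_subspace",
    "leverage_probabilities",
    "sample_columns",
    "select_features",
    "selection_error_diagnostics",
    "SelectionDiagnostics",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Sample-by-feature data matrix with optional feature names."""

    A: NDArray[np.float64]
    feature_names: list[str] | None = None

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 1:
            raise InvalidArgumentError(
                f"A must be m x n with m >= 2, n >= 1, got shape {A.shape}"
            )
        if not np.all(np.isfinite(A)):
            raise InvalidArgumentError("A contains non-finite entries")
        object.__setattr__(self, "A", A)
        if self.feature_names is not None and len(self.feature_names) != A.shape[1]:
            raise InvalidArgumentError("feature_names length must equal n")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


@dataclass(frozen=True)
class SketchResult:
    """Gaussian range sketch and approximate top-k right singular subspace."""

    G: NDArray[np.float64]
    Y: NDArray[np.float64]
    Q: NDArray[np.float64]
    Z: NDArray[np.float64]
    seed: int


@dataclass(frozen=True)
class SamplingPlan:
    """Record of one randomized column-selection draw.

    ``indices`` are the r sampled feature indices (with replacement,
    duplicates retained); ``omega`` is the n x r 0/1 selection matrix and
    ``rescale`` the diagonal of S, S(t,t) = 1/sqrt(r q_{i_t}).
    """

    r: int
    q: NDArray[np.float64]
    indices: NDArray[np.int64]
    omega: NDArray[np.float64]
    rescale: NDArray[np.float64]
    seed: int
    epsilon: float | None = None

    @property
    def S(self) -> NDArray[np.float64]:
        return np.diag(self.rescale)

    def to_dict(self) -> dict:
        """JSON-serializable plan record for provenance."""
        return {
            "seed": self.seed,
            "epsilon": self.epsilon,
            "r": self.r,
            "indices": self.indices.tolist(),
            "q": self.q.tolist(),
            "S_diagonal": self.rescale.tolist(),
        }


def number_of_features(k: int, epsilon: float) -> int:
    """Default number of selected features, r = k + ceil(k/eps) + 1.

    ``epsilon`` in (0, 1] is the allowed-error parameter: smaller epsilon
    demands more features. Always returns r > k.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidArgumentError(f"k must be a positive integer, got {k!r}")
    if not 0 < epsilon <= 1:
        raise InvalidArgumentError(f"epsilon must be in (0, 1], got {epsilon!r}")
    # guard against 2/(1/3) = 6.000000000000001-type float noise in the ceiling
    return int(k + math.ceil(k / epsilon - 1e-9) + 1)


def sketch_subspace(A: FeatureMatrix, k: int, r: int, seed: int) -> SketchResult:
    """Randomized range finder for the top-k right singular subspace of A."""
    m, n = A.shape
    if not 1 <= k <= min(m, n):
        raise InvalidArgumentError(f"k must be in [1, min(m, n)] = [1, {min(m, n)}]")
    if not k <= r <= n:
        raise InvalidArgumentError(f"r must be in [k, n] = [{k}, {n}], got {r}")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, r))
    Y = A.A @ G
    Q, R = np.linalg.qr(Y)
    # drop numerically dead directions so Q has full-rank orthonormal columns
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    B = Q.T @ A.A
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    if s.size < k or s[k - 1] <= 1e-10 * max(1.0, s[0]):
        raise RankDeficiencyError(
            f"sketch Q^T A has numerical rank < k = {k}; "
            "try another seed or a smaller k"
        )
    Z = Vt[:k].T
    return SketchResult(G=G, Y=Y, Q=Q, Z=Z, seed=seed)


def leverage_probabilities(Z: NDArray[np.float64]) -> NDArray[np.float64]:
    """Leverage-score sampling probabilities q_i = ||Z_(i)||^2 / ||Z||_F^2."""
    Z = np.asarray(Z, dtype=float)
    k = Z.shape[1]
    if np.max(np.abs(Z.T @ Z - np.eye(k))) > 1e-6:
        raise ContractViolationError("Z must have orthonormal columns")
    row_norms = np.einsum("ij,ij->i", Z, Z)
    return row_norms / row_norms.sum()


def sample_columns(q: NDArray[np.float64], r: int, seed: int) -> SamplingPlan:
    """Draw r feature indices i.i.d. with replacement from q and rescale.

    Duplicate draws are kept as distinct selected columns; deduplicating
    would break the unbiasedness E[(Omega S)(Omega S)^T] = I_n.
    """
    q = np.asarray(q, dtype=float)
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise InvalidArgumentError(f"r must be a positive integer, got {r!r}")
    if q.ndim != 1 or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
        raise InvalidArgumentError("q must be a probability vector summing to 1")
    n = q.size
    rng = np.random.default_rng(seed)
    indices = rng.choice(n, size=r, replace=True, p=q / q.sum())
    omega = np.zeros((n, r))
    omega[indices, np.arange(r)] = 1.0
    rescale = 1.0 / np.sqrt(r * q[indices])
    return SamplingPlan(
        r=int(r),
        q=q,
        indices=indices.astype(np.int64),
        omega=omega,
        rescale=rescale,
        seed=seed,
    )


def select_features(
    A: FeatureMatrix,
    k: int,
    epsilon: float = 1 / 3,
    seed: int = 0,
    r: int | None = None,
) -> tuple[NDArray[np.float64], SamplingPlan, SketchResult]:
    """Run the full randomized selection: sketch, leverage, sample, rescale.

    Returns the m x r selected-and-rescaled matrix C = A Omega S together
    with the sampling plan and sketch (all randomness recorded). The single
    ``seed`` is split deterministically: the Gaussian sketch uses ``seed``
    and the categorical sampling ``seed + 1``, so either stage can be
    reproduced on its own.
    """
    r_eff = number_of_features(k, epsilon) if r is None else int(r)
    if r_eff < 1:
        raise InvalidArgumentError(f"r must be >= 1, got {r_eff}")
    sketch = sketch_subspace(A, k=k, r=min(r_eff, A.shape[1]), seed=seed)
    q = leverage_probabilities(sketch.Z)
    plan = sample_columns(q, r=r_eff, seed=seed + 1)
    plan = SamplingPlan(
        r=plan.r,
        q=plan.q,
        indices=plan.indices,
        omega=plan.omega,
        rescale=plan.rescale,
        seed=plan.seed,
        epsilon=float(epsilon),
    )
    C = A.A[:, plan.indices] * plan.rescale
    return C, plan, sketch


def _partitions_into_k(m: int, k: int):
    """Yield all assignments of m items into exactly k nonempty unlabeled
    blocks, as restricted-growth label arrays."""
    labels = np.zeros(m, dtype=int)

    def rec(i: int, n_used: int):
        if i == m:
            if n_used == k:
                yield labels.copy()
            return
        # pruning: remaining items must be able to open the missing blocks
        if n_used + (m - i) < k:
            return
        for lab in range(min(n_used + 1, k)):
            labels[i] = lab
            yield from rec(i + 1, max(n_used, lab + 1))

    yield from rec(0, 0)


@dataclass(frozen=True)
class SelectionDiagnostics:
    """Empirical check of the clustering-error bound chain.

    ``svd_lower_bound`` is ||A - A_k||_F^2 (exact truncated SVD),
    ``objective`` is F(A, X~) for the supplied assignment, and
    ``brute_force_optimum`` (when m <= 12) is the enumerated k-means
    optimum F_opt. The chain svd_lower_bound <= F_opt <= objective must
    hold for any assignment.
    """

    objective: float
    svd_lower_bound: float
    brute_force_optimum: float | None
    chain_holds: bool


def selection_error_diagnostics(
    A: FeatureMatrix,
    assignment: NDArray[np.int64],
    k: int,
    brute_force: bool | None = None,
) -> SelectionDiagnostics:
    """Check the rank-k lower bound and (small m) the enumerated optimum.

    ``assignment`` is the clustering obtained on the selected matrix C,
    re-evaluated against the full matrix A. ``brute_force=None`` enables
    enumeration automatically when m <= 12.
    """
    from .cluster import indicator_matrix, kmeans_objective  # cycle-free import

    m = A.shape[0]
    X = indicator_matrix(np.asarray(assignment), k)
    F_A = kmeans_objective(A.A, X)
    s = np.linalg.svd(A.A, compute_uv=False)
    lower = float(np.sum(s[k:] ** 2))
    if brute_force is None:
        brute_force = m <= 12
    F_opt: float | None = None
    if brute_force:
        if m > 12:
            raise SizeLimitError(
                f"brute-force enumeration limited to m <= 12, got m = {m}"
            )
        F_opt = min(
            kmeans_objective(A.A, indicator_matrix(lab, k))
            for lab in _partitions_into_k(m, k)
        )
    tol = 1e-8 * max(1.0, F_A)
    chain = lower <= F_A + tol
    if F_opt is not None:
        chain = chain and (lower <= F_opt + tol) and (F_opt <= F_A + tol)
    return SelectionDiagnostics(
        objective=float(F_A),
        svd_lower_bound=lower,
        brute_force_optimum=F_opt,
        chain_holds=bool(chain),
    )
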
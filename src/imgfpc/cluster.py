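"""Clustering drivers, the linear-algebraic k-means objective, evaluation.

The k-means objective is used in its matrix form F(A, X) = ||A - X X^T A||_F^2,
where X is the m x k normalized cluster-indicator matrix with entries
1/sqrt(s_j) for members of cluster j. X has orthonormal columns, X^T A stacks
the scaled centroids, and F equals the within-cluster sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import (
    DegenerateInputError,
    DegeneratePartitionError,
    InvalidArgumentError,
)

__all__ = [
    "ClusterModel",
    "EvaluationReport",
    "StabilityReport",
    "indicator_matrix",
    "kmeans_objective",
    "run_kmeans",
    "run_spectral",
    "evaluate",
    "stability_analysis",
]


@dataclass(frozen=True)
class ClusterModel:
    """A k-partition of m samples with its indicator matrix and objective."""

    assignment: NDArray[np.int64]
    k: int
    centroids: NDArray[np.float64]
    objective: float

    @property
    def sizes(self) -> NDArray[np.int64]:
        return np.bincount(self.assignment, minlength=self.k)

    @property
    def X(self) -> NDArray[np.float64]:
        return indicator_matrix(self.assignment, self.k)


@dataclass(frozen=True)
class EvaluationReport:
    """Permutation-matched clustering quality against known labels."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    confusion: NDArray[np.int64]  # rows: matched predicted class, cols: truth
    label_mapping: dict[int, int]  # cluster id -> truth class index
    per_class_recall: dict[int, float] = field(default_factory=dict)


def indicator_matrix(assignment: NDArray[np.int64], k: int) -> NDArray[np.float64]:
    """Normalized cluster-indicator matrix: X_ij = 1/sqrt(s_j) if i in S_j.

    Labels are 0-based integers in {0, ..., k-1}; every cluster must be
    nonempty so that X^T X = I_k.
    """
    a = np.asarray(assignment)
    if a.ndim != 1 or a.size == 0:
        raise InvalidArgumentError("assignment must be a nonempty 1D label vector")
    if a.min() < 0 or a.max() >= k:
        raise InvalidArgumentError(f"labels must lie in [0, {k}), got {set(a.tolist())}")
    sizes = np.bincount(a, minlength=k)
    if np.any(sizes == 0):
        raise DegeneratePartitionError(
            f"empty cluster(s) {np.flatnonzero(sizes == 0).tolist()} in a {k}-partition"
        )
    X = np.zeros((a.size, k))
    X[np.arange(a.size), a] = 1.0 / np.sqrt(sizes[a])
    return X


def kmeans_objective(
    A: NDArray[np.float64],
    X: NDArray[np.float64],
    cross_check: bool = False,
) -> float:
    """Within-cluster sum of squares in matrix form, ||A - X X^T A||_F^2.

    With ``cross_check`` the pointwise form sum_i ||P_i - mu(P_i)||^2 is
    also computed and required to agree to 1e-8 relative tolerance.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != X.shape[0]:
        raise InvalidArgumentError(
            f"A has {A.shape[0]} rows but X has {X.shape[0]}"
        )
    F = float(np.linalg.norm(A - X @ (X.T @ A), "fro") ** 2)
    if cross_check:
        labels = np.argmax(X, axis=1)
        F_point = 0.0
        for j in range(X.shape[1]):
            block = A[labels == j]
            F_point += float(((block - block.mean(axis=0)) ** 2).sum())
        if abs(F - F_point) > 1e-8 * max(1.0, F):
            raise AssertionError(
                f"matrix and pointwise objectives disagree: {F} vs {F_point}"
            )
    return F


def run_kmeans(
    A: NDArray[np.float64],
    k: int,
    restarts: int = 25,
    seed: int = 0,
) -> ClusterModel:
    """Lloyd's algorithm with k-means++ starts, best of ``restarts`` runs."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m = A.shape[0]
    if not 1 <= k <= m:
        raise InvalidArgumentError(f"k must be in [1, m] = [1, {m}], got {k}")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        init="k-means++",
        random_state=np.random.RandomState(seed),
        algorithm="lloyd",
        max_iter=300,
    ).fit(A)
    labels = km.labels_.astype(np.int64)
    X = indicator_matrix(labels, k)
    return ClusterModel(
        assignment=labels,
        k=k,
        centroids=km.cluster_centers_,
        objective=kmeans_objective(A, X),
    )


def run_spectral(
    A: NDArray[np.float64],
    k: int,
    seed: int = 0,
    restarts: int = 25,
) -> ClusterModel:
    """Normalized spectral clustering.

    Gaussian affinity with bandwidth set to the median pairwise distance,
    symmetric-normalized Laplacian, embedding by the top-k eigenvectors of
    D^{-1/2} W D^{-1/2} with row normalization, then k-means on the
    embedded rows. The returned objective is the k-means objective of the
    partition measured on the original features A.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m = A.shape[0]
    if not 1 <= k <= m:
        raise InvalidArgumentError(f"k must be in [1, m] = [1, {m}], got {k}")
    if k == 1:
        labels = np.zeros(m, dtype=np.int64)
        X = indicator_matrix(labels, 1)
        return ClusterModel(
            assignment=labels, k=1, centroids=A.mean(axis=0, keepdims=True),
            objective=kmeans_objective(A, X),
        )
    d = pdist(A)
    sigma = float(np.median(d))
    if sigma <= 0:
        raise DegenerateInputError("all rows identical; spectral embedding undefined")
    W = np.exp(-squareform(d) ** 2 / (2 * sigma**2))
    deg = W.sum(axis=1)
    Dinv = 1.0 / np.sqrt(deg)
    M = Dinv[:, None] * W * Dinv[None, :]
    evals, evecs = np.linalg.eigh(M)
    U = evecs[:, -k:]  # top-k eigenvectors
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    embedded = run_kmeans(U, k, restarts=restarts, seed=seed)
    labels = embedded.assignment
    X = indicator_matrix(labels, k)
    centroids = np.stack([A[labels == j].mean(axis=0) for j in range(k)])
    return ClusterModel(
        assignment=labels, k=k, centroids=centroids,
        objective=kmeans_objective(A, X),
    )


def _match_labels(confusion: NDArray[np.int64], k: int) -> NDArray[np.int64]:
    """Cluster-to-class matching maximizing the matched trace.

    Exhaustive over permutations for k <= 6; optimal assignment (Hungarian)
    beyond — the two coincide for this objective.
    """
    if k <= 6:
        best, best_perm = -1, None
        for perm in permutations(range(k)):
            tr = sum(confusion[j, perm[j]] for j in range(k))
            if tr > best:
                best, best_perm = tr, perm
        return np.asarray(best_perm)
    rows, cols = linear_sum_assignment(-confusion)
    mapping = np.empty(k, dtype=np.int64)
    mapping[rows] = cols
    return mapping


def evaluate(
    model: ClusterModel | NDArray[np.int64],
    truth: NDArray[np.int64],
    positive_class: int = 1,
) -> EvaluationReport:
    """Accuracy, sensitivity and specificity under optimal label matching.

    Accuracy is the proportion of correctly clustered samples, maximized
    over cluster-to-class label correspondences. For k = 2, sensitivity is
    the recall of ``positive_class`` and specificity the recall of the
    other class; for k > 2 per-class recalls are reported instead.
    """
    pred = model.assignment if isinstance(model, ClusterModel) else np.asarray(model)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidArgumentError(
            f"prediction length {pred.size} != truth length {truth.size}"
        )
    classes = np.unique(truth)
    k = int(pred.max()) + 1
    if classes.size != k:
        raise InvalidArgumentError(
            f"number of true classes ({classes.size}) must equal k ({k})"
        )
    class_index = {c: j for j, c in enumerate(classes)}
    truth_idx = np.array([class_index[c] for c in truth])
    confusion = np.zeros((k, k), dtype=np.int64)  # cluster x class
    np.add.at(confusion, (pred, truth_idx), 1)
    mapping = _match_labels(confusion, k)
    matched_pred = mapping[pred]
    accuracy = float(np.mean(matched_pred == truth_idx))
    # reorder rows so row j of the reported confusion is predicted class j
    order = np.argsort(mapping)
    conf_matched = confusion[order]
    recalls = {
        int(classes[j]): float(conf_matched[j, j] / max(1, conf_matched[:, j].sum()))
        for j in range(k)
    }
    sens = spec = None
    if k == 2:
        pos = int(positive_class)
        if pos not in recalls:
            raise InvalidArgumentError(
                f"positive_class {pos} not among true classes {classes.tolist()}"
            )
        neg = int(classes[classes != pos][0])
        sens, spec = recalls[pos], recalls[neg]
    return EvaluationReport(
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        confusion=conf_matched,
        label_mapping={int(j): int(classes[mapping[j]]) for j in range(k)},
        per_class_recall=recalls,
    )


@dataclass(frozen=True)
class StabilityReport:
    """Repeated-seed behavior of randomized selection + k-means.

    ``selection_counts[i]`` counts draws of feature i over all repetitions
    (duplicates within a repetition counted); ``modal_set`` is the most
    frequent distinct-feature set and ``modal_set_share`` the proportion of
    repetitions selecting exactly that set. ``accuracies`` holds one
    permutation-matched accuracy per repetition.
    """

    n_reps: int
    r: int
    selection_counts: NDArray[np.int64]
    modal_set: tuple[int, ...]
    modal_set_share: float
    accuracies: NDArray[np.float64]

    @property
    def modal_accuracy_share(self) -> float:
        """Share of repetitions attaining the most frequent accuracy value."""
        vals, counts = np.unique(np.round(self.accuracies, 10), return_counts=True)
        return float(counts.max() / self.n_reps)


def stability_analysis(
    A: NDArray[np.float64],
    k: int,
    epsilon: float,
    truth: NDArray[np.int64],
    n_reps: int = 100,
    base_seed: int = 0,
    restarts: int = 10,
    r: int | None = None,
) -> StabilityReport:
    """Repeat select-features -> k-means -> evaluate across consecutive seeds.

    Mirrors a robustness study design: how often the same feature set is
    drawn, and how the resulting accuracy is distributed.
    """
    from .feature_select import FeatureMatrix, select_features

    if n_reps < 2:
        raise InvalidArgumentError(f"n_reps must be >= 2, got {n_reps}")
    fm = A if isinstance(A, FeatureMatrix) else FeatureMatrix(np.asarray(A, float))
    n = fm.shape[1]
    counts = np.zeros(n, dtype=np.int64)
    sets: list[tuple[int, ...]] = []
    accs = np.empty(n_reps)
    r_used = None
    for rep in range(n_reps):
        seed = base_seed + rep
        C, plan, _ = select_features(fm, k=k, epsilon=epsilon, seed=seed, r=r)
        r_used = plan.r
        np.add.at(counts, plan.indices, 1)
        sets.append(tuple(sorted(set(plan.indices.tolist()))))
        model = run_kmeans(C, k=k, restarts=restarts, seed=seed)
        accs[rep] = evaluate(model, truth).accuracy
    uniq: dict[tuple[int, ...], int] = {}
    for s in sets:
        uniq[s] = uniq.get(s, 0) + 1
    modal_set = max(uniq, key=lambda s: (uniq[s], s))
    return StabilityReport(
        n_reps=n_reps,
        r=int(r_used),
        selection_counts=counts,
        modal_set=modal_set,
        modal_set_share=uniq[modal_set] / n_reps,
        accuracies=accs,
    )
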
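"""Two-dimensional functional principal component analysis.

Each image x_i(s, t) is expanded in a tensor-product Fourier basis,

    x_i(s, t) = sum_{k,l} c_kl^(i) phi_k(s) phi_l(t) = C_i^T (phi(s) x phi(t)),

with coefficients stacked row-wise into the N x K^2 matrix C. Because the
tensor basis is orthonormal on the unit square, the covariance operator of
the centered signals is represented in coefficient space by (1/N) C^T C, and
the functional eigenproblem reduces to the matrix eigenequation

    (1/N) C^T C b = lambda b.

Eigenfunctions are beta_j(s, t) = [phi(s) x phi(t)]^T b_j and the FPC score
of image i on component j is the L2 projection xi_ij = C_i^T b_j — exact in
coefficient space, again by orthonormality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .basis import FourierBasis
from .errors import (
    ContractViolationError,
    DegenerateCohortError,
    IdentifiabilityError,
    InvalidArgumentError,
)
from .signals import ImageSignal, check_cohort, pixel_grid

__all__ = [
    "CoefficientMatrix",
    "EigenSystem",
    "ScoreMatrix",
    "fit_coefficients",
    "center_coefficients",
    "eigen_decompose",
    "eval_eigenfunction",
    "compute_scores",
    "reconstruct",
]


@dataclass(frozen=True)
class CoefficientMatrix:
    """Basis-expansion coefficients for a cohort of N images.

    ``C`` is N x K^2; row i holds the coefficients c_kl of image i in
    row-major (Kronecker) order: column ``k*K + l`` corresponds to the
    tensor function phi_{k+1}(s) phi_{l+1}(t) (0-based k, l). This matches
    the ordering of ``np.kron(phi(s), phi(t))`` for single points.

    ``column_mean`` stores the cohort mean coefficients (zero vector until
    :func:`center_coefficients` is applied), so that reconstructions can add
    the mean image back.
    """

    C: NDArray[np.float64]
    K: int
    centered: bool = False
    column_mean: NDArray[np.float64] | None = None

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[1] != self.K**2:
            raise InvalidArgumentError(
                f"C must be N x K^2 = N x {self.K ** 2}, got shape {C.shape}"
            )
        object.__setattr__(self, "C", C)
        if self.column_mean is None:
            object.__setattr__(self, "column_mean", np.zeros(self.K**2))

    @property
    def n_images(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class EigenSystem:
    """Top-J eigenpairs of the coefficient-space covariance (1/N) C^T C.

    ``eigenvalues`` are nonincreasing and nonnegative; ``coeff_vectors`` is
    K^2 x J with orthonormal columns b_j. ``total_variance`` is
    trace((1/N) C^T C), the denominator of variance-explained fractions.
    """

    eigenvalues: NDArray[np.float64]
    coeff_vectors: NDArray[np.float64]
    total_variance: float
    K: int

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass(frozen=True)
class ScoreMatrix:
    """FPC scores xi_ij (N x J) with per-component variance fractions."""

    xi: NDArray[np.float64]
    variance_explained: NDArray[np.float64]

    @property
    def n_components(self) -> int:
        return self.xi.shape[1]


def _basis_matrices(
    basis: FourierBasis, H: int, W: int
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    return basis(pixel_grid(H)), basis(pixel_grid(W))


def fit_coefficients(
    images: list[ImageSignal], basis: FourierBasis
) -> CoefficientMatrix:
    """Least-squares tensor-basis expansion of a cohort of images.

    The fit is separable: with row/column design matrices Bs (H x K) and
    Bt (W x K), the K x K coefficient block of image X solves the normal
    equations (Bs^T Bs) M (Bt^T Bt) = Bs^T X Bt, which is identical to the
    joint least-squares fit of the K^2 tensor functions on the pixel grid
    but costs O(HWK) instead of O(HW K^4).
    """
    H, W = check_cohort(images)
    K = basis.K
    if K * K > H * W:
        raise IdentifiabilityError(
            f"K^2 = {K * K} coefficients cannot be identified from {H * W} pixels"
        )
    Bs, Bt = _basis_matrices(basis, H, W)
    # Projectors solving the two 1D normal equations.
    Ps = np.linalg.solve(Bs.T @ Bs, Bs.T)  # K x H
    Pt = np.linalg.solve(Bt.T @ Bt, Bt.T).T  # W x K
    stack = np.stack([im.values for im in images])  # N x H x W
    blocks = np.einsum("kh,nhw,wl->nkl", Ps, stack, Pt)
    return CoefficientMatrix(C=blocks.reshape(len(images), K * K), K=K)


def center_coefficients(coef: CoefficientMatrix) -> CoefficientMatrix:
    """Subtract the cohort mean from each coefficient column.

    Centering in coefficient space equals centering in image space because
    the basis expansion is linear in the pixel values.
    """
    if coef.n_images < 2:
        raise DegenerateCohortError(
            f"centering needs N >= 2 images, got {coef.n_images}"
        )
    mean = coef.C.mean(axis=0)
    return CoefficientMatrix(
        C=coef.C - mean, K=coef.K, centered=True, column_mean=mean
    )


def eigen_decompose(coef: CoefficientMatrix, J: int) -> EigenSystem:
    """Solve the coefficient-space eigenequation (1/N) C^T C b = lambda b.

    Returns the top ``J`` eigenpairs, eigenvalues sorted descending and
    clipped at zero (the matrix is positive semidefinite; tiny negative
    round-off is removed). Eigenvector signs are fixed so the entry of
    largest magnitude is positive, first index winning ties, making repeated
    runs reproducible.
    """
    if not coef.centered:
        raise ContractViolationError("eigen_decompose requires centered coefficients")
    K2 = coef.K**2
    if not 1 <= J <= K2:
        raise InvalidArgumentError(f"J must be in [1, {K2}], got {J}")
    N = coef.n_images
    S = coef.C.T @ coef.C / N
    evals, evecs = np.linalg.eigh(S)  # ascending
    order = np.argsort(evals)[::-1][:J]
    lam = np.clip(evals[order], 0.0, None)
    B = evecs[:, order]
    for j in range(B.shape[1]):
        if B[np.argmax(np.abs(B[:, j])), j] < 0:
            B[:, j] = -B[:, j]
    return EigenSystem(
        eigenvalues=lam,
        coeff_vectors=B,
        total_variance=float(np.trace(S)),
        K=coef.K,
    )


def eval_eigenfunction(
    es: EigenSystem,
    basis: FourierBasis,
    j: int,
    points: ArrayLike,
) -> NDArray[np.float64]:
    """Evaluate eigenfunction beta_j(s, t) = [phi(s) x phi(t)]^T b_j.

    ``j`` is a 0-based component index; ``points`` is an array-like of
    (s, t) pairs in the unit square.
    """
    if not 0 <= j < es.n_components:
        raise InvalidArgumentError(
            f"component index {j} out of range [0, {es.n_components})"
        )
    if basis.K != es.K:
        raise ContractViolationError("basis size does not match the eigen-system")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    phi_s = basis(pts[:, 0])
    phi_t = basis(pts[:, 1])
    tensor = np.einsum("pk,pl->pkl", phi_s, phi_t).reshape(pts.shape[0], -1)
    return tensor @ es.coeff_vectors[:, j]


def compute_scores(coef: CoefficientMatrix, es: EigenSystem) -> ScoreMatrix:
    """Project each image onto the eigenfunctions.

    By orthonormality of the tensor basis the L2 inner product
    xi_ij = integral x_i beta_j reduces exactly to the coefficient inner
    product C_i^T b_j. Variance-explained fractions are lambda_j divided by
    the total coefficient variance.
    """
    if not coef.centered:
        raise ContractViolationError("compute_scores requires centered coefficients")
    if coef.C.shape[1] != es.coeff_vectors.shape[0]:
        raise ContractViolationError(
            "coefficient matrix and eigen-system have incompatible dimensions"
        )
    xi = coef.C @ es.coeff_vectors
    total = es.total_variance
    ve = es.eigenvalues / total if total > 0 else np.zeros_like(es.eigenvalues)
    return ScoreMatrix(xi=xi, variance_explained=ve)


def reconstruct(
    scores: ScoreMatrix,
    es: EigenSystem,
    basis: FourierBasis,
    coef: CoefficientMatrix,
    i: int,
    J_use: int,
    H: int,
    W: int,
) -> ImageSignal:
    """Render the truncated eigen-expansion of image i on an H x W grid.

    The reconstruction is the cohort mean image plus
    sum_{j < J_use} xi_ij beta_j. With ``J_use = 0`` this is the mean image;
    with all nonzero components it equals the basis-smoothed original.
    """
    N, J = scores.xi.shape
    if not 0 <= i < N:
        raise InvalidArgumentError(f"image index {i} out of range [0, {N})")
    if not 0 <= J_use <= J:
        raise InvalidArgumentError(f"J_use must be in [0, {J}], got {J_use}")
    coeffs = coef.column_mean + es.coeff_vectors[:, :J_use] @ scores.xi[i, :J_use]
    Bs, Bt = _basis_matrices(basis, H, W)
    values = Bs @ coeffs.reshape(es.K, es.K) @ Bt.T
    return ImageSignal(values=values, name=f"reconstruction_{i}_J{J_use}")
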
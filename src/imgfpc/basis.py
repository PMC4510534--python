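"""Orthonormal Fourier basis on the unit interval.

The one-dimensional family is the standard L2[0,1]-orthonormal trigonometric
system

    phi_1(t) = 1,
    phi_2(t) = sqrt(2) sin(2 pi t),   phi_3(t) = sqrt(2) cos(2 pi t),
    phi_4(t) = sqrt(2) sin(4 pi t),   phi_5(t) = sqrt(2) cos(4 pi t),  ...

Two-dimensional image signals are expanded in the tensor product
phi_k(s) phi_l(t); orthonormality of the 1D family makes the tensor family
orthonormal on the unit square, so covariance eigenanalysis in coefficient
space needs no Gram-matrix correction.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import InvalidArgumentError

__all__ = ["FourierBasis", "build_fourier_basis"]


class FourierBasis:
    """Ordered family of ``K`` orthonormal Fourier functions on [0, 1].

    Parameters
    ----------
    K
        Number of basis functions. The family is ordered constant first,
        then sine/cosine pairs of increasing frequency.
    """

    def __init__(self, K: int):
        if not isinstance(K, (int, np.integer)) or K < 1:
            raise InvalidArgumentError(f"K must be a positive integer, got {K!r}")
        self.K = int(K)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FourierBasis(K={self.K})"

    def __call__(self, points: ArrayLike) -> NDArray[np.float64]:
        """Evaluate all K functions at ``points``.

        Returns an array of shape ``(len(points), K)`` whose column ``j``
        holds phi_{j+1} evaluated at the points.
        """
        t = np.atleast_1d(np.asarray(points, dtype=float))
        if t.ndim != 1:
            raise InvalidArgumentError("points must be one-dimensional")
        out = np.empty((t.size, self.K))
        out[:, 0] = 1.0
        for j in range(1, self.K):
            freq = 2.0 * np.pi * ((j + 1) // 2)
            if j % 2 == 1:  # even position in 1-based ordering -> sine
                out[:, j] = np.sqrt(2.0) * np.sin(freq * t)
            else:
                out[:, j] = np.sqrt(2.0) * np.cos(freq * t)
        return out

    def gram(self, n_grid: int = 512) -> NDArray[np.float64]:
        """Numerical Gram matrix via the midpoint rule on ``n_grid`` cells.

        For a well-conditioned basis this is the identity to high accuracy;
        useful as a self-check.
        """
        t = (np.arange(n_grid) + 0.5) / n_grid
        B = self(t)
        return B.T @ B / n_grid


def build_fourier_basis(K: int) -> FourierBasis:
    """Build the orthonormal Fourier family with ``K`` functions per axis."""
    return FourierBasis(K)
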
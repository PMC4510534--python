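"""Synthetic cohorts with known group structure and functional components.

Cohorts are defined in tensor-Fourier coefficient space: each group has a
smooth mean surface given by a coefficient vector, within-group variation is
carried by a few fixed orthonormal tensor-basis functions with known score
standard deviations, and pixel noise is i.i.d. Gaussian. Defining fixtures
in coefficient space makes the ground-truth eigenfunctions and eigenvalues
exact, so parameter-recovery tests have an analytic reference that real
histology data cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .basis import FourierBasis
from .errors import InvalidArgumentError
from .signals import ImageSignal, pixel_grid

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_feature_matrix",
    "write_cohort_png",
]


def _default_score_slots(K: int, n: int) -> list[int]:
    """Coefficient slots carrying within-group variation: the diagonal
    tensor functions phi_2(s)phi_2(t), phi_3(s)phi_3(t), ... (skipping the
    constant), which are mutually orthonormal."""
    if n > K - 1:
        raise InvalidArgumentError(
            f"need K >= {n + 1} for {n} default variation components, got K={K}"
        )
    return [(j + 1) * K + (j + 1) for j in range(n)]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic image cohort.

    Attributes
    ----------
    n_per_group
        Group sizes; the cohort has sum(n_per_group) images.
    H, W
        Pixel grid dimensions.
    K
        Tensor-Fourier basis size per axis for means and components.
    group_mean_coeffs
        One coefficient vector of length K^2 (or K x K block) per group,
        defining that group's smooth mean surface.
    score_sds
        Standard deviations of the within-group functional scores; one
        entry per variation component. The population eigenvalues of the
        centered cohort (single group, zero noise) are score_sds**2.
    score_coeff_vectors
        Optional K^2 x J orthonormal coefficient matrix whose columns are
        the variation components; defaults to unit vectors at diagonal
        tensor slots (phi_2 phi_2, phi_3 phi_3, ...).
    noise_sd
        Pixel-level i.i.d. Gaussian noise standard deviation.
    seed
        Seed for all randomness in the cohort.
    """

    n_per_group: tuple[int, ...]
    H: int = 32
    W: int = 32
    K: int = 8
    group_mean_coeffs: tuple[NDArray[np.float64], ...] = ()
    score_sds: tuple[float, ...] = ()
    score_coeff_vectors: NDArray[np.float64] | None = None
    noise_sd: float = 0.05
    seed: int = 0
    group_names: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if len(self.n_per_group) == 0 or any(n < 1 for n in self.n_per_group):
            raise InvalidArgumentError("all group sizes must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.H < 2 or self.W < 2:
            raise InvalidArgumentError("grid must be at least 2 x 2")
        K2 = self.K**2
        means = []
        for g, c in enumerate(self.group_mean_coeffs):
            c = np.asarray(c, dtype=float).reshape(-1)
            if c.size != K2:
                raise InvalidArgumentError(
                    f"group {g} mean has {c.size} coefficients, expected K^2 = {K2}"
                )
            means.append(c)
        if len(means) != len(self.n_per_group):
            raise InvalidArgumentError(
                "need one mean coefficient vector per group"
            )
        object.__setattr__(self, "group_mean_coeffs", tuple(means))
        if self.score_coeff_vectors is not None:
            B = np.asarray(self.score_coeff_vectors, dtype=float)
            if B.shape != (K2, len(self.score_sds)):
                raise InvalidArgumentError(
                    f"score_coeff_vectors must be K^2 x {len(self.score_sds)}"
                )
            if np.max(np.abs(B.T @ B - np.eye(B.shape[1]))) > 1e-8:
                raise InvalidArgumentError(
                    "score_coeff_vectors columns must be orthonormal"
                )
            object.__setattr__(self, "score_coeff_vectors", B)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group))

    def component_matrix(self) -> NDArray[np.float64]:
        """K^2 x J orthonormal matrix of variation components."""
        J = len(self.score_sds)
        if self.score_coeff_vectors is not None:
            return self.score_coeff_vectors
        B = np.zeros((self.K**2, J))
        for j, slot in enumerate(_default_score_slots(self.K, J)):
            B[slot, j] = 1.0
        return B


def generate_cohort(spec: CohortSpec) -> tuple[list[ImageSignal], NDArray[np.int64]]:
    """Sample a cohort: image = group mean + score-weighted components + noise.

    Image i of group g is mean_g(s,t) + sum_j z_ij beta*_j(s,t) + eps, with
    z_ij ~ N(0, score_sds_j^2) and eps i.i.d. N(0, noise_sd^2) per pixel,
    rendered on the H x W pixel-center grid. Values are not clipped to
    [0, 1], preserving Gaussianity. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    basis = FourierBasis(spec.K)
    Bs = basis(pixel_grid(spec.H))
    Bt = basis(pixel_grid(spec.W))
    comp = spec.component_matrix()
    sds = np.asarray(spec.score_sds, dtype=float)
    images: list[ImageSignal] = []
    labels: list[int] = []
    idx = 0
    for g, n_g in enumerate(spec.n_per_group):
        mean_c = spec.group_mean_coeffs[g]
        for _ in range(n_g):
            coeff = mean_c.copy()
            if sds.size:
                z = rng.normal(0.0, sds)
                coeff = coeff + comp @ z
            values = Bs @ coeff.reshape(spec.K, spec.K) @ Bt.T
            if spec.noise_sd > 0:
                values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
            name = (
                spec.group_names[g] if g < len(spec.group_names) else f"g{g}"
            )
            images.append(ImageSignal(values=values, name=f"{name}_{idx:04d}"))
            labels.append(g)
            idx += 1
    return images, np.asarray(labels, dtype=np.int64)


def generate_feature_matrix(
    m: int,
    k_clusters: int,
    n_features: int,
    n_informative: int,
    separation: float,
    seed: int = 0,
    informative_sd: float = 1.0,
    distractor_sd: float = 1.0,
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Gaussian-mixture feature matrix for clustering and selection tests.

    Cluster centers live in the first ``n_informative`` coordinates and are
    rescaled so their minimum pairwise distance equals ``separation``; the
    remaining coordinates are pure noise with ``distractor_sd``. Labels are
    balanced (sizes differ by at most one). Deterministic given ``seed``.
    """
    if not (1 <= n_informative <= n_features):
        raise InvalidArgumentError("need 1 <= n_informative <= n_features")
    if not (1 <= k_clusters <= m):
        raise InvalidArgumentError("need 1 <= k_clusters <= m")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k_clusters, n_informative))
    if k_clusters > 1 and separation > 0:
        raw = rng.standard_normal((k_clusters, n_informative))
        d = np.sqrt(((raw[:, None] - raw[None, :]) ** 2).sum(-1))
        min_d = d[np.triu_indices(k_clusters, 1)].min()
        if min_d <= 0:
            raw += np.arange(k_clusters)[:, None]  # break exact coincidence
            d = np.sqrt(((raw[:, None] - raw[None, :]) ** 2).sum(-1))
            min_d = d[np.triu_indices(k_clusters, 1)].min()
        centers = raw * (separation / min_d)
    labels = np.arange(m) % k_clusters
    A = np.empty((m, n_features))
    A[:, :n_informative] = centers[labels] + rng.normal(
        0.0, informative_sd, size=(m, n_informative)
    )
    if n_features > n_informative:
        A[:, n_informative:] = rng.normal(
            0.0, distractor_sd, size=(m, n_features - n_informative)
        )
    return A, labels.astype(np.int64)


def write_cohort_png(
    images: list[ImageSignal], out_dir: str | Path
) -> list[Path]:
    """Write images as 8-bit grayscale PNGs (values clipped to [0, 1]).

    Exercises the real file-reading path end-to-end; quantization error is
    at most 1/255 per pixel for values already in [0, 1].
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, im in enumerate(images):
        arr = np.clip(im.values, 0.0, 1.0)
        png = np.round(arr * 255).astype(np.uint8)
        p = out_dir / f"{im.name or f'image_{i:04d}'}.png"
        iio.imwrite(p, png)
        paths.append(p)
    return paths
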
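"""Image signals on a normalized spatial domain.

An image is treated as a discretely sampled function x(s, t) on the unit
square. The pixel grid is mapped to pixel-center coordinates
s_h = (h + 1/2)/H, t_w = (w + 1/2)/W so that analysis parameters are
independent of resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .errors import CohortInconsistencyError, InvalidArgumentError

__all__ = ["ImageSignal", "pixel_grid", "check_cohort"]


def pixel_grid(n: int) -> NDArray[np.float64]:
    """Pixel-center coordinates of a uniform n-cell grid on [0, 1]."""
    return (np.arange(n) + 0.5) / n


@dataclass(frozen=True)
class ImageSignal:
    """One sample's pixel grid on the normalized domain [0,1] x [0,1].

    Attributes
    ----------
    values
        H x W array of pixel intensities (dimensionless; file readers
        rescale integer images to [0, 1], but any finite values are legal).
    name
        Optional sample identifier (e.g. source filename stem).
    """

    values: NDArray[np.float64]
    name: str = field(default="", compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise InvalidArgumentError(
                f"image must be a 2D array with H >= 2 and W >= 2, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("image contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def grid_s(self) -> NDArray[np.float64]:
        """Row (vertical, s-axis) pixel-center coordinates."""
        return pixel_grid(self.values.shape[0])

    @property
    def grid_t(self) -> NDArray[np.float64]:
        """Column (horizontal, t-axis) pixel-center coordinates."""
        return pixel_grid(self.values.shape[1])


def check_cohort(images: list[ImageSignal]) -> tuple[int, int]:
    """Validate that all images share one pixel grid; return (H, W)."""
    if len(images) == 0:
        raise CohortInconsistencyError("empty cohort")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        detail = ", ".join(
            f"{im.name or i}: {im.shape}" for i, im in enumerate(images)
        )
        raise CohortInconsistencyError(
            f"images have mixed dimensions {sorted(shapes)} ({detail})"
        )
    return images[0].shape
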
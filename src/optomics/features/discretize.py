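"""Fixed-bin-width gray-level discretization.

level(x) = floor((x - min_edge) / bin_width) + 1, all levels >= 1.
Fixed bin width (rather than a fixed bin count) keeps the physical meaning
of one gray level constant across samples of the same channel, so texture
features are comparable between samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscreteImage:
    """Integer gray-level image, levels 1..n_levels."""

    levels: np.ndarray
    bin_width: float
    min_edge: float

    @property
    def n_levels(self) -> int:
        return int(self.levels.max())


def discretize_fbw(image: np.ndarray, bin_width: float,
                   min_edge: float | None = None) -> DiscreteImage:
    """Discretize with fixed bin width; ``min_edge`` defaults to the image
    minimum (so the lowest occupied level is 1)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if min_edge is None:
        min_edge = float(image.min())
    levels = np.floor((image - min_edge) / bin_width).astype(np.int64) + 1
    if levels.min() < 1:
        raise ValueError("min_edge above image minimum produces levels < 1")
    return DiscreteImage(levels=levels, bin_width=bin_width,
                         min_edge=float(min_edge))
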
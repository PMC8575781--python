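"""Texture matrix construction on discretized 2D images.

Conventions (documented here once; the feature formulas in ``texture.py``
and the brute-force oracles in the test suite share them):

- GLCM: distance 1, four angles (0, 45, 90, 135 degrees), symmetric;
  each angle's count matrix is normalized then the four are averaged, so
  entries sum to 1.
- GLRLM: maximal runs of equal level along the same four directions; the
  per-direction count matrices are merged (summed) into one matrix.
- GLSZM: 8-connected zones of equal level (rotation invariant, no angles).
- GLDM: dependence = number of Chebyshev-distance-1 neighbours whose level
  differs from the centre by at most alpha (default 0); the matrix column
  index is dependence + 1, so an isolated pixel lands in column 1.
- NGTDM: 3x3 neighbourhood excluding the centre; border pixels average over
  their available neighbours.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .discretize import DiscreteImage

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
#: (row, col) steps matching the four GLCM angles at distance 1.
DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class NGTDMData:
    """Neighbourhood gray-tone difference data per occupied level."""

    levels: np.ndarray  # occupied gray levels i
    n: np.ndarray       # pixel counts n_i
    p: np.ndarray       # occurrence probabilities p_i = n_i / N
    s: np.ndarray       # summed absolute differences s_i


@dataclass
class TextureMatrixSet:
    """All five texture matrices for one discretized sub-image."""

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm: NGTDMData
    n_levels: int


def _as_levels(image: DiscreteImage | np.ndarray) -> np.ndarray:
    levels = image.levels if isinstance(image, DiscreteImage) else np.asarray(image)
    if levels.ndim != 2:
        raise ValueError("texture matrices are defined on 2D images")
    if levels.size < 2:
        raise ValueError("image with < 2 pixels: texture features undefined")
    if levels.min() < 1:
        raise ValueError("gray levels must be >= 1")
    return levels.astype(np.int64)


def glcm_matrix(image: DiscreteImage | np.ndarray,
                distance: int = 1,
                angles: tuple[float, ...] = GLCM_ANGLES,
                symmetric: bool = True) -> np.ndarray:
    """Angle-averaged normalized symmetric co-occurrence matrix, (N, N)."""
    levels = _as_levels(image)
    n_levels = int(levels.max())
    counts = graycomatrix(
        (levels - 1).astype(np.uint8 if n_levels <= 256 else np.uint16),
        distances=[distance], angles=list(angles), levels=n_levels,
        symmetric=symmetric, normed=False,
    ).astype(np.float64)  # (N, N, 1, n_angles)
    per_angle = counts[:, :, 0, :]
    sums = per_angle.sum(axis=(0, 1))
    valid = sums > 0
    if not valid.any():
        raise ValueError("no valid pixel pairs for GLCM")
    normed = per_angle[:, :, valid] / sums[valid]
    return normed.mean(axis=2)


def _run_lengths_1d(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal runs in a 1D array."""
    if line.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    change = np.nonzero(np.diff(line))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return line[starts], ends - starts


def _diagonals(levels: np.ndarray, anti: bool) -> list[np.ndarray]:
    a = np.fliplr(levels) if anti else levels
    h, w = a.shape
    return [np.diagonal(a, offset=k) for k in range(-(h - 1), w)]


def glrlm_matrix(image: DiscreteImage | np.ndarray) -> np.ndarray:
    """Run-length count matrix merged over the four directions, (N, R)."""
    levels = _as_levels(image)
    n_levels = int(levels.max())
    max_run = max(levels.shape)
    mat = np.zeros((n_levels, max_run), dtype=np.float64)

    lines: list[np.ndarray] = []
    lines.extend(levels)                    # horizontal
    lines.extend(levels.T)                  # vertical
    lines.extend(_diagonals(levels, False))  # main diagonals
    lines.extend(_diagonals(levels, True))   # anti-diagonals
    for line in lines:
        vals, lens = _run_lengths_1d(np.asarray(line))
        np.add.at(mat, (vals - 1, lens - 1), 1.0)
    return mat


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def glszm_matrix(image: DiscreteImage | np.ndarray) -> np.ndarray:
    """Size-zone count matrix over 8-connected zones, (N, S)."""
    levels = _as_levels(image)
    n_levels = int(levels.max())
    max_size = levels.size
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for i in range(1, n_levels + 1):
        labelled, n_zones = ndimage.label(levels == i, structure=_EIGHT_CONN)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        np.add.at(mat, (i - 1, sizes - 1), 1.0)
    # trim trailing all-zero size columns (keeps matrices small)
    occupied = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : occupied.max() + 1] if occupied.size else mat[:, :1]


def gldm_matrix(image: DiscreteImage | np.ndarray, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence count matrix, (N, 9) in 2D."""
    levels = _as_levels(image)
    n_levels = int(levels.max())
    h, w = levels.shape
    dependence = np.zeros((h, w), dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full((h, w), np.iinfo(np.int64).min, dtype=np.int64)
            rs = slice(max(dr, 0), h + min(dr, 0))
            cs = slice(max(dc, 0), w + min(dc, 0))
            rs_src = slice(max(-dr, 0), h + min(-dr, 0))
            cs_src = slice(max(-dc, 0), w + min(-dc, 0))
            shifted[rs, cs] = levels[rs_src, cs_src]
            dependence += np.abs(shifted - levels) <= alpha
    n_dep = 9  # dependence size = neighbours + centre, 1..9 in 2D
    mat = np.zeros((n_levels, n_dep), dtype=np.float64)
    np.add.at(mat, (levels.ravel() - 1, dependence.ravel()), 1.0)
    return mat


def ngtdm_matrix(image: DiscreteImage | np.ndarray) -> NGTDMData:
    """Neighbourhood gray-tone difference data."""
    levels = _as_levels(image)
    n_levels = int(levels.max())
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    fl = levels.astype(np.float64)
    nb_sum = ndimage.convolve(fl, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(np.ones_like(fl), kernel, mode="constant",
                              cval=0.0)
    nb_mean = nb_sum / nb_cnt
    diff = np.abs(fl - nb_mean)

    idx = levels.ravel() - 1
    n = np.bincount(idx, minlength=n_levels).astype(np.float64)
    s = np.bincount(idx, weights=diff.ravel(), minlength=n_levels)
    p = n / levels.size
    return NGTDMData(levels=np.arange(1, n_levels + 1), n=n, p=p, s=s)


def compute_texture_matrices(image: DiscreteImage | np.ndarray,
                             gldm_alpha: int = 0) -> TextureMatrixSet:
    levels = _as_levels(image)
    return TextureMatrixSet(
        glcm=glcm_matrix(levels),
        glrlm=glrlm_matrix(levels),
        glszm=glszm_matrix(levels),
        gldm=gldm_matrix(levels, alpha=gldm_alpha),
        ngtdm=ngtdm_matrix(levels),
        n_levels=int(levels.max()),
    )
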
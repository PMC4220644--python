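"""Gray-level co-occurrence matrix (GLCM) and Haralick-style texture features.

The GLCM P(i, j) is the normalized frequency with which a pixel of gray
level i and a pixel of gray level j occur separated by a fixed offset
(distance d, direction theta).  Directions follow the classical texture
convention, measured counterclockwise with image rows increasing downward:

    theta =   0 deg -> ( 0, +d)   horizontal, rightward
    theta =  45 deg -> (-d, +d)   up-right diagonal
    theta =  90 deg -> (-d,  0)   vertical, upward
    theta = 135 deg -> (-d, -d)   up-left diagonal

Four features are computed from P: entropy (natural log by default),
angular second moment, variance about the gray-level mean, and the
row/column-marginal correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError, InvalidArgumentError, InvalidInputError

__all__ = ["GLCMatrix", "TextureFeatures", "compute_glcm", "texture_features"]

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMatrix:
    P: np.ndarray  # (levels, levels) float, sums to 1
    levels: int
    distance: int
    angle: int
    symmetric: bool


@dataclass(frozen=True)
class TextureFeatures:
    entropy: float
    angular_second_moment: float
    variance: float
    correlation: float


def compute_glcm(
    gray: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    levels: int = 256,
    symmetric: bool = False,
    mask: np.ndarray | None = None,
) -> GLCMatrix:
    """Co-occurrence matrix of a gray image for one (distance, angle) offset.

    If ``mask`` is given, only pairs whose *both* pixels are inside the mask
    are counted.  ``symmetric`` also counts every pair reversed.
    """
    g = np.asarray(gray)
    if g.ndim != 2:
        raise InvalidInputError(f"expected 2-D gray image, got shape {g.shape}")
    if angle not in _OFFSETS:
        raise InvalidArgumentError(f"angle must be one of {sorted(_OFFSETS)}, got {angle}")
    if distance < 1:
        raise InvalidArgumentError("distance must be >= 1")
    if g.min() < 0 or g.max() >= levels:
        raise InvalidInputError(f"gray values must lie in [0, {levels - 1}]")

    dr, dc = (distance * o for o in _OFFSETS[angle])
    h, w = g.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateImageError("image too small for the requested offset")
    src = g[r0:r1, c0:c1].astype(np.int64)
    dst = g[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int64)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        src, dst = src[valid], dst[valid]
        if src.size == 0:
            raise DegenerateImageError("mask admits no valid pixel pairs")
    counts = np.bincount(
        (src.ravel() * levels + dst.ravel()), minlength=levels * levels
    ).reshape(levels, levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateImageError("no valid pixel pairs")
    return GLCMatrix(
        P=counts / total,
        levels=levels,
        distance=distance,
        angle=angle,
        symmetric=symmetric,
    )


def texture_features(glcm: GLCMatrix, log_base: float = math.e) -> TextureFeatures:
    """Entropy, angular second moment, variance, and correlation of a GLCM.

    * entropy = -sum P log P (0 log 0 := 0), natural log by default;
    * ASM = sum P**2;
    * variance = sum_i (i - mu)**2 p_x(i) with mu the i-marginal mean;
    * correlation = (sum_ij i*j*P(i,j) - mu_x mu_y) / (sigma_x sigma_y),
      defined as 0 when either marginal SD vanishes.
    """
    P = np.asarray(glcm.P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidInputError("GLCM must be square")
    if abs(P.sum() - 1.0) > 1e-9 or (P < 0).any():
        raise InvalidInputError("GLCM must be normalized (entries >= 0, sum 1)")

    nz = P[P > 0]
    entropy = float(-(nz * (np.log(nz) / math.log(log_base))).sum())
    asm = float((P**2).sum())

    i = np.arange(P.shape[0], dtype=float)
    px = P.sum(axis=1)  # row (i) marginal
    py = P.sum(axis=0)  # column (j) marginal
    mu = float((i * px).sum())
    variance = float(((i - mu) ** 2 * px).sum())

    mu_x, mu_y = mu, float((i * py).sum())
    sigma_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sigma_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))
    if sigma_x * sigma_y == 0.0:
        correlation = 0.0
    else:
        cross = float((np.outer(i, i) * P).sum())
        correlation = (cross - mu_x * mu_y) / (sigma_x * sigma_y)
    return TextureFeatures(
        entropy=entropy,
        angular_second_moment=asm,
        variance=variance,
        correlation=correlation,
    )
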
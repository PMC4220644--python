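"""Morisita's index of dispersion over a fixed sub-image (quadrat) grid.

The binary pattern is divided into n equal sub-images (default 12, as a
3x4 grid for landscape images) and the index

    I_d = n * (sum_i X_i**2 - N) / (N * (N - 1))

is computed from the per-cell foreground counts X_i (N = sum X_i).  Under
complete spatial randomness E[I_d] is approximately 1; maximal clumping
into one cell gives I_d = n and a perfectly even split gives
(N - n) / (N - 1).  Note the index *increases with aggregation* of the
pattern (see docs/methods.md for a discussion of this polarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientForegroundError, InvalidArgumentError

__all__ = ["MorisitaResult", "morisita_index", "default_grid"]


@dataclass(frozen=True)
class MorisitaResult:
    index_value: float
    n_subimages: int
    total_pixels: int
    per_cell_counts: np.ndarray  # row-major cell order, ints
    grid_rows: int
    grid_cols: int


def default_grid(height: int, width: int) -> tuple[int, int]:
    """12 equal sub-images: 3x4 for landscape, 4x3 for portrait."""
    return (3, 4) if width >= height else (4, 3)


def morisita_index(
    pattern: np.ndarray,
    grid_rows: int | None = None,
    grid_cols: int | None = None,
) -> MorisitaResult:
    """Morisita index of a binary pattern over a grid of equal sub-images.

    The image is cropped at the bottom/right to dimensions divisible by the
    grid so every cell has equal area (an assumption of the formula).
    """
    pat = np.asarray(pattern, dtype=bool)
    h, w = pat.shape
    if grid_rows is None or grid_cols is None:
        grid_rows, grid_cols = default_grid(h, w)
    if grid_rows < 1 or grid_cols < 1 or grid_rows * grid_cols < 2:
        raise InvalidArgumentError("grid must have at least 2 cells")
    if grid_rows > h or grid_cols > w:
        raise InvalidArgumentError("grid larger than image")

    ch, cw = h // grid_rows, w // grid_cols
    cropped = pat[: ch * grid_rows, : cw * grid_cols]
    counts = (
        cropped.reshape(grid_rows, ch, grid_cols, cw)
        .sum(axis=(1, 3))
        .astype(np.int64)
        .ravel()
    )
    n = grid_rows * grid_cols
    N = int(counts.sum())
    if N < 2:
        raise InsufficientForegroundError(
            f"need >= 2 foreground pixels after cropping, got {N}"
        )
    idx = n * (float((counts.astype(float) ** 2).sum()) - N) / (N * (N - 1.0))
    return MorisitaResult(
        index_value=idx,
        n_subimages=n,
        total_pixels=N,
        per_cell_counts=counts,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
    )
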
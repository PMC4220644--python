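"""Box-counting fractal dimension (multi-origin) and lacunarity of binary patterns.

For each grid origin, boxes of increasing side s tile the plane and the
number of boxes containing any foreground pixel is counted; the dimension
estimate is -1 times the slope of the OLS regression of log(count) on
log(s).  Averaging over several grid origins (the first is always (0, 0),
the rest are seeded uniform offsets below the smallest box size) minimizes
grid-placement effects.  Lacunarity is the average, over all grid sizes
and origins, of the coefficient of variation of the per-box foreground
mass, computed over boxes lying fully inside the image (so all boxes have
equal area); low lacunarity means the pattern fills space uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyPatternError,
    InvalidArgumentError,
    RegressionDegenerateError,
)

__all__ = [
    "BoxGridSpec",
    "FractalResult",
    "default_sizes",
    "box_counts",
    "box_masses",
    "fractal_dimension",
    "lacunarity",
]


@dataclass(frozen=True)
class BoxGridSpec:
    """Box-size ladder and origin-sampling parameters.

    ``sizes`` must be strictly increasing box side lengths (pixels).
    ``n_origins`` grids are used: origin (0, 0) first, the rest drawn
    uniformly (seeded) from offsets below the smallest size.
    """

    sizes: tuple[int, ...]
    n_origins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) < 2:
            raise InvalidArgumentError("need at least 2 box sizes")
        if any(s < 1 for s in sizes):
            raise InvalidArgumentError("box sizes must be >= 1")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise InvalidArgumentError("box sizes must be strictly increasing")
        if self.n_origins < 1:
            raise InvalidArgumentError("n_origins must be >= 1")

    def origins(self) -> list[tuple[int, int]]:
        out = [(0, 0)]
        if self.n_origins > 1:
            rng = np.random.default_rng(self.seed)
            smallest = self.sizes[0]
            offs = rng.integers(0, smallest, size=(self.n_origins - 1, 2))
            out.extend((int(a), int(b)) for a, b in offs)
        return out


@dataclass(frozen=True)
class FractalResult:
    per_origin_D: list[float]
    mean_D: float
    lacunarity: float | None
    per_origin_counts: list[dict[int, int]]  # size -> occupied-box count
    regression_points: list[tuple[float, float]] = field(default_factory=list)


def default_sizes(shape: tuple[int, int]) -> tuple[int, ...]:
    """Geometric ladder: powers of 2 from 2 up to a quarter of the short side."""
    top = min(shape) // 4
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise InvalidArgumentError(f"image too small for a box-size ladder: {shape}")
    return tuple(sizes)


def _check_grid_fits(pattern: np.ndarray, size: int, origin: tuple[int, int]) -> None:
    if size < 1 or size > max(pattern.shape):
        raise InvalidArgumentError(f"box size {size} outside [1, max(image dims)]")
    orow, ocol = origin
    if not (0 <= orow < size and 0 <= ocol < size):
        raise InvalidArgumentError("origin offsets must satisfy 0 <= offset < size")


def box_counts(pattern: np.ndarray, size: int, origin: tuple[int, int] = (0, 0)) -> int:
    """Number of grid boxes (side ``size``, shifted by ``origin``) containing
    at least one foreground pixel.

    The grid tiles the whole plane starting from (-origin), so every pixel
    belongs to exactly one box; an empty pattern yields 0.
    """
    pat = np.asarray(pattern, dtype=bool)
    _check_grid_fits(pat, size, origin)
    rows, cols = np.nonzero(pat)
    if rows.size == 0:
        return 0
    br = (rows + origin[0]) // size
    bc = (cols + origin[1]) // size
    n_cols = (pat.shape[1] + origin[1] + size - 1) // size + 1
    return int(np.unique(br * n_cols + bc).size)


def _integral_image(pat: np.ndarray) -> np.ndarray:
    s = np.zeros((pat.shape[0] + 1, pat.shape[1] + 1), dtype=np.int64)
    s[1:, 1:] = pat.cumsum(axis=0).cumsum(axis=1)
    return s


def box_masses(
    pattern: np.ndarray, size: int, origin: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Foreground-pixel mass of every grid box lying fully inside the image.

    Boxes clipped by the image border are excluded so that all returned
    masses refer to equal-area boxes; empty boxes are included.  Returned
    in row-major box order.
    """
    pat = np.asarray(pattern, dtype=bool)
    _check_grid_fits(pat, size, origin)
    h, w = pat.shape
    starts_r = np.arange((-origin[0]) % size, h - size + 1, size)
    starts_c = np.arange((-origin[1]) % size, w - size + 1, size)
    if starts_r.size == 0 or starts_c.size == 0:
        return np.zeros(0, dtype=np.int64)
    s = _integral_image(pat)
    a = starts_r[:, None]
    b = starts_c[None, :]
    masses = s[a + size, b + size] - s[a, b + size] - s[a + size, b] + s[a, b]
    return masses.ravel()


def fractal_dimension(pattern: np.ndarray, grid: BoxGridSpec) -> FractalResult:
    """Multi-origin box-counting dimension estimate.

    Per origin: OLS of log(occupied boxes) on log(size) over sizes with
    nonzero counts, D = -slope; the final estimate is the mean over
    origins.  Deterministic for a fixed grid seed.
    """
    pat = np.asarray(pattern, dtype=bool)
    if pat.sum() < 2:
        raise EmptyPatternError("need >= 2 foreground pixels for a dimension estimate")
    per_origin_D: list[float] = []
    per_origin_counts: list[dict[int, int]] = []
    regression_points: list[tuple[float, float]] = []
    for k, origin in enumerate(grid.origins()):
        counts = {s: box_counts(pat, s, origin) for s in grid.sizes}
        usable = [(s, c) for s, c in counts.items() if c > 0]
        if len(usable) < 2:
            raise RegressionDegenerateError(
                f"fewer than 2 sizes with nonzero counts at origin {origin}"
            )
        xs = np.log([s for s, _ in usable])
        ys = np.log([c for _, c in usable])
        slope = np.polyfit(xs, ys, 1)[0]
        per_origin_D.append(float(-slope))
        per_origin_counts.append(counts)
        if k == 0:
            regression_points = list(zip(xs.tolist(), ys.tolist()))
    return FractalResult(
        per_origin_D=per_origin_D,
        mean_D=float(np.mean(per_origin_D)),
        lacunarity=None,
        per_origin_counts=per_origin_counts,
        regression_points=regression_points,
    )


def lacunarity(pattern: np.ndarray, grid: BoxGridSpec, mode: str = "cv") -> float:
    """Average coefficient of variation of box masses over all sizes and origins.

    ``cv`` returns the mean of sigma/mu (population SD over the box-mass
    population of each grid); ``cv_squared`` the mean of (sigma/mu)**2.
    Grids with no fully-inside box, or with zero total mass inside, are
    skipped.
    """
    if mode not in ("cv", "cv_squared"):
        raise InvalidArgumentError(f"unknown lacunarity mode {mode!r}")
    pat = np.asarray(pattern, dtype=bool)
    if not pat.any():
        raise EmptyPatternError("lacunarity undefined for an empty pattern")
    cvs: list[float] = []
    for origin in grid.origins():
        for size in grid.sizes:
            masses = box_masses(pat, size, origin)
            if masses.size == 0:
                continue
            mu = masses.mean()
            if mu == 0:
                continue
            cv = masses.std() / mu  # population SD
            cvs.append(cv * cv if mode == "cv_squared" else cv)
    if not cvs:
        raise EmptyPatternError("no usable grid placements for lacunarity")
    return float(np.mean(cvs))
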
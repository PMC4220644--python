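"""Synthetic binary fixtures and histology-like tissue images with known ground truth.

Two families of generators live here:

* Analytic fixtures (filled rectangles, Sierpinski carpets, point patterns)
  whose dispersion / fractal properties are known in closed form, used to
  validate the estimators.

* A tissue-image generator emulating a lobular parenchyma partitioned by
  thick interlobular connective septa, with a tunable density of thin
  intralobular branches.  Lobules are Voronoi cells of random sites; septa
  are drawn along the cell boundaries; branches are biased random walks
  growing inward from the septa.  The construction makes the connective
  area fraction (mostly septum thickness) and the branching complexity
  (branch density) independently tunable, so two cohorts can share the same
  connective amount while differing in structural complexity.

Connective tissue is rendered DARK in the red channel, emulating a blue
trichrome stain (blue absorbs red light); parenchyma is bright.  All
generators are pure functions of their spec (the seed is part of the spec):
the same spec yields a bit-identical image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import CalibrationError, InvalidArgumentError

__all__ = [
    "SyntheticTissueSpec",
    "TissueTruth",
    "make_filled_rect",
    "make_sierpinski_carpet",
    "make_point_pattern",
    "make_tissue_image",
    "mean_area_fraction",
    "calibrate_area_fraction",
    "calibrate_matched_specs",
]

# Rendered intensities (R, G, B): connective dark in red, bluish overall;
# parenchyma bright in red.  Values give ~115 gray levels of red-channel
# separation, large against the default stain noise.
_CONNECTIVE_RGB = (90, 115, 185)
_PARENCHYMA_RGB = (205, 175, 165)

_INWARD_BIAS = 0.6  # biased-random-walk weight toward the lobule centre
_SEED_MOD = 2_147_483_647


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Parameters of one synthetic tissue image.

    Attributes
    ----------
    width, height : int
        Image size in pixels (>= 64 each).
    n_lobules : int
        Number of Voronoi sites (parenchyma lobules), >= 2.
    septum_thickness : float
        Width in pixels of the interlobular septa (>= 1).
    branch_density : float
        Expected number of intralobular branch initiations per lobule
        (Poisson-distributed per lobule), >= 0.
    branch_length_mean : float
        Mean branch length in pixels (individual lengths ~ Normal with
        SD = mean/3, floored at 3 steps).
    branch_width : float
        Width in pixels of the branches (>= 1).
    stain_noise_sd : float
        SD of additive Gaussian intensity noise, per channel.
    seed : int
        RNG seed; part of the spec, so equal specs give identical images.
    """

    width: int = 256
    height: int = 256
    n_lobules: int = 12
    septum_thickness: float = 14.0
    branch_density: float = 4.0
    branch_length_mean: float = 25.0
    branch_width: float = 2.0
    stain_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise InvalidArgumentError("width and height must be >= 64")
        if self.n_lobules < 2:
            raise InvalidArgumentError("n_lobules must be >= 2")
        if self.septum_thickness < 1:
            raise InvalidArgumentError("septum_thickness must be >= 1")
        if self.branch_density < 0:
            raise InvalidArgumentError("branch_density must be >= 0")
        if self.branch_length_mean < 1:
            raise InvalidArgumentError("branch_length_mean must be >= 1")
        if self.branch_width < 1:
            raise InvalidArgumentError("branch_width must be >= 1")
        if self.stain_noise_sd < 0:
            raise InvalidArgumentError("stain_noise_sd must be >= 0")
        if not (0 <= int(self.seed) < _SEED_MOD):
            raise InvalidArgumentError("seed must be in [0, 2**31 - 1)")


@dataclass(frozen=True)
class TissueTruth:
    """Ground truth accompanying a generated tissue image."""

    mask: np.ndarray  # bool (height, width), True = connective tissue
    area_fraction: float
    n_branches: int
    spec: SyntheticTissueSpec


def make_filled_rect(width: int, height: int) -> np.ndarray:
    """All-foreground rectangle, shape (height, width)."""
    if width < 1 or height < 1:
        raise InvalidArgumentError("width and height must be positive")
    return np.ones((height, width), dtype=bool)


def make_sierpinski_carpet(order: int) -> np.ndarray:
    """Sierpinski carpet of side 3**order with exactly 8**order foreground pixels.

    Built by repeated Kronecker product with the 3x3 cell that has its
    centre removed; the self-similarity dimension is log 8 / log 3.
    """
    if not (1 <= int(order) <= 7) or int(order) != order:
        raise InvalidArgumentError("order must be an integer in [1, 7]")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    carpet = np.ones((1, 1), dtype=bool)
    for _ in range(int(order)):
        carpet = np.kron(carpet, cell)
    return carpet


def _default_point_grid(width: int, height: int) -> tuple[int, int]:
    # 12 sub-images, nearest-to-square factorization by orientation
    return (3, 4) if width >= height else (4, 3)


def make_point_pattern(
    n_points: int,
    layout: str,
    n_clusters: int = 3,
    cluster_sd: float = 5.0,
    width: int = 160,
    height: int = 120,
    seed: int = 0,
    grid_rows: int | None = None,
    grid_cols: int | None = None,
) -> np.ndarray:
    """Binary pattern with exactly ``n_points`` foreground pixels.

    layout:
      * ``uniform`` — complete spatial randomness (distinct pixels).
      * ``clustered`` — points scattered N(0, cluster_sd) around
        ``n_clusters`` uniformly placed centres (collisions redrawn).
      * ``single_cell`` — all points inside one cell of the quadrat grid
        used by the Morisita index (default 12 cells).
    """
    if n_points < 1:
        raise InvalidArgumentError("n_points must be >= 1")
    if layout not in ("uniform", "clustered", "single_cell"):
        raise InvalidArgumentError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    pattern = np.zeros((height, width), dtype=bool)

    if layout == "uniform":
        if n_points > width * height:
            raise InvalidArgumentError("n_points exceeds image capacity")
        flat = rng.choice(width * height, size=n_points, replace=False)
        pattern.flat[flat] = True
        return pattern

    if layout == "single_cell":
        rows, cols = (grid_rows, grid_cols)
        if rows is None or cols is None:
            rows, cols = _default_point_grid(width, height)
        cell_h, cell_w = height // rows, width // cols
        if n_points > cell_h * cell_w:
            raise InvalidArgumentError(
                f"n_points={n_points} exceeds sub-image capacity {cell_h * cell_w}"
            )
        r0 = int(rng.integers(rows)) * cell_h
        c0 = int(rng.integers(cols)) * cell_w
        flat = rng.choice(cell_h * cell_w, size=n_points, replace=False)
        pattern[r0 + flat // cell_w, c0 + flat % cell_w] = True
        return pattern

    # clustered
    if n_clusters < 1:
        raise InvalidArgumentError("clustered layout requires n_clusters >= 1")
    centers = np.column_stack(
        [rng.uniform(0, height, n_clusters), rng.uniform(0, width, n_clusters)]
    )
    placed: set[tuple[int, int]] = set()
    attempts = 0
    while len(placed) < n_points:
        attempts += 1
        if attempts > 200 * n_points:
            raise InvalidArgumentError("could not place distinct clustered points")
        c = centers[rng.integers(n_clusters)]
        r = int(round(np.clip(c[0] + rng.normal(0, cluster_sd), 0, height - 1)))
        q = int(round(np.clip(c[1] + rng.normal(0, cluster_sd), 0, width - 1)))
        placed.add((r, q))
    rows_, cols_ = zip(*placed)
    pattern[list(rows_), list(cols_)] = True
    return pattern


def _voronoi_boundary(labels: np.ndarray) -> np.ndarray:
    """1-pixel boundary lines between Voronoi cells (label changes right/down)."""
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    return b


def _dilate_to_width(points: np.ndarray, width: float) -> np.ndarray:
    """Thicken a set of pixels to a stroke of the given width via EDT."""
    if not points.any():
        return points
    if width <= 1:
        return points
    dist = ndimage.distance_transform_edt(~points)
    return dist < width / 2.0


def _grow_branch(
    start: np.ndarray,
    target: np.ndarray,
    length: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Biased random walk from a septum pixel toward the lobule centre.

    Each step is unit length; the direction mixes the inward unit vector
    (weight 0.6) with a uniformly random unit vector, producing thin
    tortuous branches.
    """
    pos = start.astype(float)
    pts: list[tuple[int, int]] = []
    for _ in range(length):
        inward = target - pos
        nrm = float(np.hypot(*inward))
        if nrm < 1.0:
            break
        theta = rng.uniform(0.0, 2.0 * np.pi)
        step = _INWARD_BIAS * inward / nrm + (1 - _INWARD_BIAS) * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        snrm = float(np.hypot(*step))
        if snrm == 0.0:
            continue
        pos = pos + step / snrm
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            break
        pts.append((r, c))
    return pts


def make_tissue_image(spec: SyntheticTissueSpec) -> tuple[np.ndarray, TissueTruth]:
    """Render one synthetic tissue image and its ground truth.

    Returns
    -------
    rgb : uint8 array (height, width, 3)
        Bright-field-like image; connective tissue dark in the red channel.
    truth : TissueTruth
        Exact connective-tissue mask, its area fraction, and branch count.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    sites = np.column_stack(
        [rng.uniform(0, h, spec.n_lobules), rng.uniform(0, w, spec.n_lobules)]
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()])
    _, lab = cKDTree(sites).query(pix)
    labels = lab.reshape(h, w)

    boundary = _voronoi_boundary(labels)
    dist_to_boundary = ndimage.distance_transform_edt(~boundary)
    # per-image thickness jitter: septum width varies between sections, and
    # it keeps the mean area fraction a smooth function of the nominal
    # thickness (the EDT threshold alone is quantized to distance shells)
    eff_thickness = max(1.0, spec.septum_thickness + rng.uniform(-0.5, 0.5))
    septa = dist_to_boundary < eff_thickness / 2.0
    if eff_thickness <= 1:
        septa = boundary.copy()

    # Branches: Poisson(branch_density) starts per lobule, drawn on the
    # lobule's stretch of boundary, walking inward toward the site.
    branch_pts = np.zeros((h, w), dtype=bool)
    n_branches = 0
    bc = np.argwhere(boundary)
    blab = labels[boundary]
    for lobule in range(spec.n_lobules):
        k = int(rng.poisson(spec.branch_density)) if spec.branch_density > 0 else 0
        own = np.flatnonzero(blab == lobule)
        for _ in range(k):
            if own.size == 0:
                break
            start = bc[own[int(rng.integers(own.size))]]
            length = max(3, int(round(rng.normal(spec.branch_length_mean,
                                                 spec.branch_length_mean / 3.0))))
            pts = _grow_branch(start, sites[lobule], length, (h, w), rng)
            if pts:
                n_branches += 1
                rs, cs = zip(*pts)
                branch_pts[list(rs), list(cs)] = True
    branches = _dilate_to_width(branch_pts, spec.branch_width)

    mask = septa | branches

    fg = np.array(_CONNECTIVE_RGB, dtype=float)
    bg = np.array(_PARENCHYMA_RGB, dtype=float)
    img = np.where(mask[..., None], fg, bg)
    if spec.stain_noise_sd > 0:
        img = img + rng.normal(0.0, spec.stain_noise_sd, img.shape)
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = TissueTruth(
        mask=mask,
        area_fraction=float(mask.mean()),
        n_branches=n_branches,
        spec=spec,
    )
    return rgb, truth


def _derived_seeds(base_seed: int, n: int) -> list[int]:
    return [(base_seed + 1_000_003 * (i + 1)) % _SEED_MOD for i in range(n)]


def mean_area_fraction(
    spec: SyntheticTissueSpec,
    n_seeds: int = 10,
    seeds: list[int] | None = None,
) -> float:
    """Truth-mask area fraction averaged over seed replicates of ``spec``."""
    if seeds is None:
        seeds = _derived_seeds(spec.seed, n_seeds)
    vals = [
        make_tissue_image(dataclasses.replace(spec, seed=s))[1].area_fraction
        for s in seeds
    ]
    return float(np.mean(vals))


def _bisect_thickness(
    spec: SyntheticTissueSpec,
    target: float,
    seeds: list[int],
    lo: float,
    hi: float,
    tol: float,
    max_iter: int = 22,
    measure=None,
) -> tuple[SyntheticTissueSpec, float]:
    """Bisection on septum_thickness; area fraction is monotone in it."""
    if measure is None:
        measure = lambda sp, sd: mean_area_fraction(sp, seeds=sd)  # noqa: E731
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cand = dataclasses.replace(spec, septum_thickness=mid)
        f = measure(cand, seeds)
        if abs(f - target) <= tol:
            return cand, f
        if f < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    cand = dataclasses.replace(spec, septum_thickness=0.5 * (lo + hi))
    return cand, measure(cand, seeds)


def calibrate_area_fraction(
    spec: SyntheticTissueSpec,
    target_fraction: float,
    tolerance: float = 0.02,
    n_seeds: int = 10,
) -> SyntheticTissueSpec:
    """Adjust the spec so its mean truth-mask area fraction hits a target.

    Septum thickness is bisected first (the dominant area contribution);
    if the target lies outside the reachable range, branch width is
    adjusted as well.  The returned spec's mean area fraction over
    ``n_seeds`` seed replicates lies within ``tolerance`` of the target.
    """
    if not (0.0 < target_fraction < 1.0):
        raise CalibrationError(
            f"target_fraction must lie strictly in (0, 1); got {target_fraction} "
            "(septa are always present, fraction 0 is unreachable)"
        )
    seeds = _derived_seeds(spec.seed, n_seeds)
    t_lo, t_hi = 1.0, max(2.0, min(spec.width, spec.height) / 4.0)

    f_lo = mean_area_fraction(dataclasses.replace(spec, septum_thickness=t_lo), seeds=seeds)
    f_hi = mean_area_fraction(dataclasses.replace(spec, septum_thickness=t_hi), seeds=seeds)

    work = spec
    if target_fraction < f_lo - tolerance:
        # thinnest septa still too much area: thin the branches too
        work = dataclasses.replace(spec, septum_thickness=t_lo, branch_width=1.0)
        f = mean_area_fraction(work, seeds=seeds)
        if target_fraction < f - tolerance:
            raise CalibrationError(
                f"target {target_fraction:.3f} below reachable minimum {f:.3f} "
                f"(septum_thickness={t_lo}, branch_width=1)"
            )
        return work
    if target_fraction > f_hi + tolerance:
        widened = dataclasses.replace(spec, branch_width=max(spec.branch_width, 10.0))
        f = mean_area_fraction(
            dataclasses.replace(widened, septum_thickness=t_hi), seeds=seeds
        )
        if target_fraction > f + tolerance:
            raise CalibrationError(
                f"target {target_fraction:.3f} above reachable maximum {f:.3f} "
                f"(septum_thickness={t_hi}, branch_width>=10)"
            )
        work = widened

    cand, f = _bisect_thickness(work, target_fraction, seeds, t_lo, t_hi, tolerance / 2.0)
    if abs(f - target_fraction) > tolerance:
        raise CalibrationError(
            f"bisection stalled at fraction {f:.4f} for target {target_fraction:.4f} "
            f"(tolerance {tolerance})"
        )
    return cand


def calibrate_matched_specs(
    spec_to_adjust: SyntheticTissueSpec,
    reference_spec: SyntheticTissueSpec,
    tolerance: float = 0.0005,
    n_seeds_coarse: int = 16,
    n_seeds_fine: int = 512,
    measure=None,
) -> SyntheticTissueSpec:
    """Match one cohort's mean area fraction to another's.

    Uses common random numbers: both cohorts are measured on the SAME seed
    list, so the shared Voronoi geometry (sites and septum jitter are drawn
    before branches) cancels out of the difference and the residual cohort
    mean offset is driven far below the per-image SD.  A coarse bisection
    on few seeds brackets the septum thickness; a fine bisection on many
    seeds finishes.

    ``measure(spec, seeds) -> float`` defaults to the truth-mask mean area
    fraction; pass a segmentation-based measure to match the fraction a
    downstream pipeline will actually observe.
    """
    if measure is None:
        measure = lambda sp, sd: mean_area_fraction(sp, seeds=sd)  # noqa: E731
    seeds_fine = _derived_seeds(reference_spec.seed, n_seeds_fine)
    seeds_coarse = seeds_fine[:n_seeds_coarse]
    target_coarse = measure(reference_spec, seeds_coarse)
    t_lo, t_hi = 1.0, max(2.0, min(spec_to_adjust.width, spec_to_adjust.height) / 4.0)
    coarse, _ = _bisect_thickness(
        spec_to_adjust, target_coarse, seeds_coarse, t_lo, t_hi, tol=0.002,
        measure=measure,
    )
    target_fine = measure(reference_spec, seeds_fine)
    t_mid = coarse.septum_thickness
    fine, f = _bisect_thickness(
        coarse,
        target_fine,
        seeds_fine,
        max(t_lo, t_mid - 1.5),
        min(t_hi, t_mid + 1.5),
        tol=tolerance,
        max_iter=12,
        measure=measure,
    )
    if abs(f - target_fine) > tolerance:
        raise CalibrationError(
            f"matched calibration stalled: fraction {f:.4f} vs target {target_fine:.4f}"
        )
    return fine
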
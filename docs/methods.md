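# Methods

cbmorph quantifies the spatial organization of a segmented tissue pattern —
typically the connective-tissue network of a bright-field histological
section — beyond its sheer amount. The motivating observation is that two
conditions can deposit a *comparable amount* of connective tissue while
arranging it very differently (e.g. thick interlobular septa only, versus
septa plus many thin intralobular branches). First-order measures such as
the area fraction are blind to this; dispersion, texture, and fractal
descriptors are not.

## Segmentation

Input images are 8-bit RGB bright-field fields. For blue trichrome stains
the connective tissue absorbs red light, so the red channel carries the
best connective/parenchyma contrast and is used for all downstream
processing. Thresholding is Otsu's criterion by default (the cut
maximizing between-class variance of the 256-bin integer histogram, with a
manual override), with an explicit `polarity` switch because which side of
the cut is tissue depends on the stain; `dark_foreground` is the default.
A geometric filter then removes artifact profiles: connected components
(8-connectivity default) are kept only if their pixel area lies in
`[min_area, max_area]` and their circularity `4πA/P²` (Crofton perimeter)
lies in `[min_circularity, max_circularity]`. Circularity is clipped at
1.0: the Crofton estimate underestimates the perimeter of very small
components, which would otherwise push the ratio above 1 and make the
default upper bound silently active. Shipped defaults pass everything
except components under 20 px. Thinning to the 1-pixel skeleton uses the
Zhang–Suen algorithm (topology preserving, deterministic, idempotent);
fractal descriptors are computed on the skeleton by default (`use_skeleton`
flag), because box counting on a thick mask mostly measures stroke width.

## Morisita's index of dispersion

The binary pattern is divided into `n` equal sub-images (default 12: 3×4
for landscape fields, 4×3 for portrait; the image is cropped bottom/right
to grid-divisible dimensions so all quadrats have equal area, which the
formula assumes). With `X_i` foreground pixels in quadrat `i` and
`N = ΣX_i`,

    I_d = n (ΣX_i² − N) / (N (N − 1)).

Under complete spatial randomness E[I_d] ≈ 1; the maximum `n` is attained
when all pixels fall in one quadrat, the minimum `(N−n)/(N−1)` when they
split evenly. Note that under this standard quadrat formula the index
**increases with aggregation** (clumping), not with spreading; prose
descriptions sometimes state the opposite polarity, so cbmorph documents
and tests the formula's actual behavior. No small-sample correction is
applied. Reported I_d values in the source literature for this class of
data (≈0.03–0.08) lie below the analytic minimum of the formula for large
N, so absolute values from other software are not comparable; only
relative orderings computed within cbmorph are meaningful.

## Gray-level co-occurrence texture

The GLCM `P(i,j)` is the normalized frequency of gray-level pairs at a
fixed offset. Offsets follow the classical texture convention (θ
counterclockwise, rows increasing downward): 0° = (0,+d), 45° = (−d,+d),
90° = (−d,0), 135° = (−d,−d). Defaults are d = 1, θ = 0°, asymmetric, 256
levels, matching the common defaults of classic texture plugins; all are
configurable, and pair counting can optionally be restricted to the
segmented foreground. Four features are computed:

* entropy `−ΣΣ P log P` (natural log by default, base 2 optional);
* angular second moment `ΣΣ P²`;
* variance `Σ_i (i−μ)² p_x(i)` with μ the i-marginal mean — the
  occasionally printed form `(1−μ)²` is a known typographical corruption
  (it would be constant in i and j) and Haralick's `(i−μ)²` is used;
* correlation `(ΣΣ ij P − μ_x μ_y)/(σ_x σ_y)` with the marginal means/SDs,
  defined as 0 when a marginal SD vanishes.

## Box-counting dimension and lacunarity

For a grid of boxes of side `s` shifted by an origin offset, the number of
boxes containing any skeleton pixel is counted; the dimension estimate is
−1 × the OLS slope of log(count) against log(s). The default size ladder
is powers of two from 2 px up to a quarter of the short image side (even
spacing in log space); sizes with zero count are dropped. To minimize
grid-placement effects the count is repeated from 10 origins — (0,0) plus
9 seeded uniform offsets below the smallest box size — and the final D is
the mean over origins. Exact power laws are recovered exactly: a filled
square gives D = 2 and a 1-px line D = 1 on power-of-two ladders at origin
(0,0), and the order-5 Sierpinski carpet gives log 8/log 3 ≈ 1.8928.

Lacunarity is the average, over all grid sizes and origins, of the
coefficient of variation σ/μ of the per-box pixel mass. Boxes clipped by
the image border are excluded (mass statistics must compare equal-area
boxes), empty interior boxes are included, and the population SD is used
(the boxes of a grid are the full population, not a sample). A
`cv_squared` mode returns (σ/μ)², the convention of some fractal-analysis
tools; the choice is recorded in output metadata. Whether border boxes and
empty boxes enter the statistic varies between published tools and is
rarely stated; these defaults are declared choices, not inferences.

## Group statistics

Per-image features are aggregated to subject level (mean over a subject's
images) before any test, so the sampling unit is the subject. Per feature:
one-way ANOVA (classical between/within F); Dunnett two-sided comparisons
of each group against a designated control using the pooled within-group
variance, with the family-wise adjusted p estimated by seeded Monte-Carlo
simulation of the max-|t| null distribution (default 10⁵ draws; exact
Dunnett tables cover few group/size configurations, while the MC error is
controllable and the estimate is clipped from below by the unadjusted t
p-value so monotonicity holds exactly); Bonferroni-adjusted pooled t-tests
for selected pairs; and the empirical ROC curve for a designated pair of
groups, with AUC by the trapezoidal rule (equal to the Mann–Whitney
statistic with ties credited ½) and the conventional accuracy bands
assigned left-closed/right-open: <0.6 no value, [0.6,0.7) poor, [0.7,0.8)
fair, [0.8,0.9) good, ≥0.9 excellent. The ROC direction is declared per
feature (higher fractal D marks the more-branched condition, lower
lacunarity likewise); α = 0.05 throughout. Equal-variance t statistics are
used throughout, matching the classical ANOVA framing.

## Synthetic tissue model

No public histology accompanies this problem, so validation uses a
generative model whose ground truth is exact:

* **Lobules** are Voronoi cells of `n_lobules` uniform random sites.
* **Septa** are the cell boundaries thickened to `septum_thickness` px via
  a distance transform. Each image jitters the nominal thickness by
  U(−0.5, 0.5) px: real septa vary between sections, and the jitter makes
  the mean area fraction a smooth function of the thickness parameter
  (the distance threshold alone moves in discrete shells).
* **Intralobular branches**: per lobule, Poisson(`branch_density`) branches
  start at random points of that lobule's boundary and grow as biased
  random walks toward the lobule centre (inward weight 0.6, unit steps,
  length ~ N(mean, mean/3) floored at 3), thickened to `branch_width` px —
  thin, tortuous strands.
* **Rendering**: connective pixels get RGB (90, 115, 185) (dark in red,
  bluish), parenchyma (205, 175, 165), plus additive Gaussian stain noise
  (SD 6 by default), clipped to [0, 255].

All generators are pure functions of their spec (the seed is a spec
field). The defaults (256×256 px, 12 lobules, septum thickness 14 px,
branch density 4, branch length 25 px, width 2 px) give a connective area
fraction near 0.30, the order observed in normal carotid-body tissue.

The construction's point is that **area fraction and branching complexity
are independently tunable**. `calibrate_area_fraction` bisects the septum
thickness (and branch width if needed) to hit a target fraction.
`calibrate_matched_specs` matches one cohort's mean fraction to another's
using common random numbers — both cohorts are measured on the same seed
list, so the shared Voronoi geometry cancels from the difference — and the
matched-cohort study calibrates on the *segmented* fraction (through the
full red-channel → Otsu → filter chain), because that is the quantity the
downstream test sees and segmentation bias need not be identical between
cohorts. With 512 paired calibration seeds and a stopping tolerance of
5×10⁻⁴ the residual cohort mean offset is of order 5×10⁻⁴ — a few percent
of the per-image SD (≈0.02) — so the area-fraction ANOVA between matched
cohorts stays essentially at its nominal false-positive rate.

What the generator does **not** emulate: cell nuclei, vessels,
innervation, staining gradients, shading, out-of-focus blur, or 3-D
context. Passing tests therefore demonstrate correctness of the
estimators and of the study logic on patterns with the stated gross
morphology, not segmentation robustness on real slides.

## Problem sizes and numerics

The replicated matched-cohort study runs at 192×192 px, 10 lobules, 20
subjects per cohort, 50 replicates, with a (2,4,8,16,32) box ladder and 4
origins inside the replicate loop (10 origins are the default elsewhere);
these sizes keep the full study in the order of a minute while leaving the
fractal-D effect between cohorts at ≈6 per-image SDs. The Dunnett
calibration experiment uses 2000 simulated 3-group null studies with
2×10⁴ MC draws per study. Box masses use an integral image; GLCM counting
uses vectorized bincount. Ties in Otsu's criterion take the smallest
maximizing cut. Degenerate inputs raise typed errors (constant image under
Otsu, empty pattern for lacunarity, < 2 foreground pixels for Morisita or
box-counting) rather than returning silent zeros; an image whose
segmentation comes out empty yields a flagged NaN record.

## Known limitations

* Absolute Morisita and lacunarity values are convention-dependent
  (grid geometry, border/empty-box handling); only within-package
  comparisons are meaningful.
* The box-counting regression is unweighted OLS over the whole ladder; no
  automatic scaling-range selection is attempted.
* Welch-type unequal-variance tests are not offered.
* The segmentation stage assumes flat-field illumination and a stain whose
  connective component is dark in the red channel; other stains need the
  manual threshold/polarity settings or an upstream color deconvolution.
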
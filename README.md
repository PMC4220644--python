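# cbmorph

Morphometric analysis of connective-tissue patterns in bright-field
histological images.

Tissue remodeling often changes *how* a component is arranged long before —
or even without — changing *how much* of it there is. The classic example
this package targets is the carotid body, whose glomic lobules are
delimited by interlobular connective septa from which thin intralobular
branches depart: aging and chronic opiate exposure both roughly double the
connective amount, but only one of them produces a markedly more complex
branching pattern. First-order morphometry (area fraction) cannot tell
such conditions apart; spatial-statistics descriptors can.

cbmorph implements, end to end:

* **Segmentation** — red-channel extraction (blue trichrome stains are dark
  in red), Otsu or manual thresholding with explicit polarity, geometric
  artifact filtering by component area and circularity (4πA/P²), and
  Zhang–Suen skeletonization.
* **Morisita's index of dispersion** `I_d = n(ΣX_i² − N)/(N(N−1))` over a
  12-quadrat grid — quadrat-count aggregation statistic.
* **GLCM texture features** — entropy, angular second moment, variance,
  correlation of the gray-level co-occurrence matrix P(i,j) at a
  configurable offset (d, θ).
* **Fractal descriptors** — multi-origin box-counting dimension
  (D = −slope of log count vs. log box size, averaged over 10 grid
  origins) and lacunarity (mean coefficient of variation of box masses
  over all grid sizes and origins) of the binary skeleton.
* **Group statistics** — one-way ANOVA, Dunnett comparisons vs. a control
  group (Monte-Carlo max-|t| adjustment), Bonferroni selected pairs, and
  ROC curves with AUC accuracy bands (poor/fair/good/excellent).
* **Synthetic tissue generator** — Voronoi-lobule images with septa and
  random-walk intralobular branches whose connective area fraction and
  branching complexity are *independently* tunable, with exact ground
  truth, used to validate every estimator and the study design itself.

See `docs/methods.md` for the model details and numerical conventions.

## Worked example

```python
import cbmorph as cb

# a synthetic field with known ground truth
spec = cb.SyntheticTissueSpec(width=192, height=192, seed=5)
rgb, truth = cb.make_tissue_image(spec)
print(f"truth area fraction: {truth.area_fraction:.4f}")

rec = cb.analyze_image(rgb)
print(f"segmented area fraction: {rec.area_fraction:.4f}")
print(f"Morisita I_d: {rec.morisita_index:.4f}")
print(f"entropy: {rec.entropy:.4f}   ASM: {rec.asm:.6f}")
print(f"fractal D: {rec.fractal_D:.4f}   lacunarity: {rec.lacunarity:.4f}")
```

prints

```
truth area fraction: 0.3678
segmented area fraction: 0.3678
Morisita I_d: 1.1124
entropy: 7.1775   ASM: 0.001121
fractal D: 1.1404   lacunarity: 1.7950
```

The segmented fraction tracks the generator's truth to well under a
pixel per thousand. `I_d` slightly above 1 means the connective pixels
are mildly aggregated relative to spatial randomness at the 12-quadrat
scale. D ≈ 1.14 is the
box-counting dimension of the skeleton — between a smooth curve (1) and a
plane-filling structure (2); more intralobular branching pushes it up,
which is exactly the contrast the matched-cohort study exploits.

From the shell, the same pipeline is available as:

```sh
cbmorph simulate --n-per-group 20 --seed 1 --out data/      # synthetic cohorts
cbmorph segment data/images/A000.tif --out seg/             # mask + skeleton
cbmorph study --manifest data/manifest.csv --out results/   # features + stats
cbmorph config-init                                         # write default TOML
```

`study` writes `features.csv` (per image), `subjects.csv`,
`summary.csv` (group means ± s.e.m. with ANOVA/Dunnett/Bonferroni p
values) and `roc.csv` (AUC + accuracy band per feature for the designated
group pair).

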
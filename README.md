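# leafmorph

Quantitative morphometrics of leaf-margin serration, plus reporter-fluorescence
quantification, for studies that compare leaf shape between genotypes along a
developmental series — e.g. wild-type *Arabidopsis* rosette leaves against
smooth-margined mutants such as GDP-L-fucose-deficient *mur1*, with boundary
reporters like *pCUC2::RFP* read out in the tooth sinuses.

## What it computes

**Dissection index (DI).** For a closed leaf silhouette with perimeter *P* and
area *A*, the isoperimetric dissection is

    leaf_DI = P² / (4π A)

which is 1 for a circle and grows with both margin complexity and blade
elongation. To isolate serration from global blade shape, the same statistic
is computed on the leaf's **alpha hull** — a generalization of the convex hull
(Delaunay triangles with circumradius ≤ α) that bridges the tooth sinuses while
following the blade outline and petiole — and the final, genotype-comparable
statistic is the ratio

    DI = leaf_DI / ahull_DI

so that DI ≈ 1 for a smooth blade of any proportions and increases with
serration depth.

**Margin landmarks.** The petiole/lamina junction (base) and leaf apex are
located from the contour's principal axis and the concave petiole neck; tooth
apices are curvature maxima along the margin, flanking sinuses the nearest
curvature minima, and tooth height is the perpendicular distance from the apex
to the sinus chord. Blade length (base-to-apex distance, petiole excluded)
serves as the developmental-stage proxy.

**Trajectories and comparisons.** Per-leaf values are plotted against blade
length with LOESS (tricube-weighted local regression) curves per genotype;
genotypes are compared by Student's t-tests within blade-length classes
(defaults 200–400, 400–600, 600–800 µm). Mean silhouettes average
base-aligned, arclength-resampled contours without rescaling. Phenotype counts
(e.g. cotyledon fusion classes) become frequency tables.

**Reporter quantification.** Seeded, semi-automatic zone quantification:
a robust local background (median and 1.4826×MAD of an annulus around a
user-supplied seed) defines the threshold `background + k·spread`; the
connected component of above-threshold pixels containing the seed is the zone,
and the readout is the accumulated background-subtracted intensity. Nuclear
reporters are measured as the mean intensity of the 12 most intense nuclei
(difference-of-Gaussians detection, disk means).

**Synthetic ground truth.** Every stage is validated against a parametric
generator: ovate blades with a petiole, raised-cosine marginal teeth with
analytically known apices/sinuses/heights, smooth band-limited boundary noise,
developmental cohorts with isometric scaling, and fluorescence images with
known background fields, zone signals and nucleus intensities.

## Worked example

```python
from leafmorph import (LeafParams, generate_leaf, leaf_di,
                       detect_teeth, find_base_and_apex, blade_length)

params = LeafParams(blade_length=1000, n_teeth=3, tooth_height_frac=0.25,
                    noise_amp=5, seed=11)
contour, truth = generate_leaf(params)

rec = leaf_di(contour, alpha="auto")
print(f"leaf_DI  = {rec.leaf_DI:.4f}")
print(f"ahull_DI = {rec.ahull_DI:.4f}")
print(f"DI       = {rec.DI:.4f}   (alpha = {rec.alpha:.0f} um)")

base, apex = find_base_and_apex(contour)
print(f"blade length = {blade_length(contour, base, apex):.1f} um")
for t in sorted(detect_teeth(contour), key=lambda t: (t.side, t.rank_from_base)):
    print(f"  {t.side:>5} tooth {t.rank_from_base}: height {t.height:.1f} um")
```

prints

```
leaf_DI  = 2.0084
ahull_DI = 1.8383
DI       = 1.0926   (alpha = 263 um)
blade length = 997.7 um
   left tooth 1: height 48.8 um
   left tooth 2: height 41.0 um
   left tooth 3: height 28.2 um
  right tooth 1: height 45.3 um
  right tooth 2: height 39.4 um
  right tooth 3: height 36.4 um
```

`leaf_DI = 2.01` reflects both the elongated blade and its serration;
normalizing by the alpha hull's `ahull_DI = 1.84` leaves `DI = 1.09`, the pure
serration signal (a smooth convex blade gives DI ≈ 1.00). The detected tooth
heights recover the generator's ground truth to within a few percent despite
0.5% boundary noise.

A shell interface mirrors the library:
`leafmorph generate leaf|cohort|fluor`, `leafmorph measure di|landmarks`,
`leafmorph analyze trajectory`, `leafmorph quantify zone|nuclei`.

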
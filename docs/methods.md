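# Methods

This note documents the models, defaults and numerical choices behind
`leafmorph`, and what the synthetic benchmarks do and do not establish about
real micrographs.

## Shape statistic

The dissection index of a closed contour is the isoperimetric ratio
`P²/(4πA)` (1 for a circle, >1 otherwise). The final statistic divides the
leaf's ratio by the same ratio computed on its alpha hull, so global blade
proportions cancel and only margin structure remains. Properties relied on
throughout: scale invariance (exact), rigid-motion invariance (exact up to
floating point), DI ≈ 1 for convex silhouettes, and strictly monotone response
to tooth height at fixed blade geometry and fixed alpha.

Two caveats are inherent to the statistic, not implementation artifacts:

* **A petiole-bearing silhouette is not convex.** The hull bridges the two
  concave notches where the blade meets the petiole, which alone raises DI of
  a perfectly smooth petiole-bearing leaf to ≈ 1.04–1.05. The "DI ≈ 1 for
  smooth leaves" normalization statement is exact only for convex outlines;
  comparisons between genotypes are unaffected because the notch contribution
  is common to both.
* **Absolute DI values depend on alpha and on contour sampling density.**
  Only orderings and ratios across genotypes are treated as reproducible.

## Alpha hull

The computable realization is the alpha *shape*: Delaunay-triangulate the
contour points (resampled to 1024 vertices so hull resolution is independent
of pixel size), keep triangles with circumradius ≤ α, take area as the sum of
kept-triangle areas and perimeter as the total length of edges used by exactly
one kept triangle. The segment-bounded alpha shape and the arc-bounded alpha
hull agree in perimeter/area in the dense-sampling limit this pipeline
operates in. Near-degenerate triangles (circumradius overflow) count as
infinite circumradius and are dropped unless α = ∞ is requested, in which case
the result is exactly the convex hull.

The default α is 0.2× the bounding-box diagonal: large enough to bridge
sinuses and the petiole notch, small enough to follow the global outline.
Two failure regimes bound its validity and sized several defaults below:

* α must exceed the largest *empty* circumcircle of the sampled interior,
  which is roughly the blade half-width — and can reach half-width × (1 +
  tooth-height fraction) when an interior circle bulges through a point-free
  sinus indentation. Below that, the kept triangulation develops interior
  holes and the hull perimeter explodes. With the default blade aspect ratio
  (width 0.34 × length) the auto-α margin is ≈ 15% for petiole-bearing
  leaves across the whole tooth-height range used.
* For nearly circular contours every circumradius equals the circle radius,
  so the 0.2×diagonal heuristic (≈ 0.57 r) is always too small; such shapes
  need an explicit α larger than the radius.

## Synthetic leaf model

The blade is a convex ovate outline made of two half-ellipses sharing the
widest chord at 40% of the span from the base, attached to a
constant-width petiole with a semicircular tip. Defaults: blade length
1000 µm, blade width 340 µm, petiole 250 × 60 µm, three teeth per side. The
elongated aspect (≈ 2.9) was chosen so the auto-alpha hull is hole-free (see
above) with margin to spare; the petiole is well under 25% of the blade width
so the neck detector has slack on both sides.

Teeth are raised-cosine bumps displaced along the outward normal of the
smooth outline. Tooth height is `tooth_height_frac` × the local blade
half-width; the bump support half-width is `tooth_width_frac` × the
inter-tooth spacing (capped at the three-teeth spacing so sparse margins
still carry locally sharp teeth). At the default `tooth_width_frac = 0.5`
consecutive supports exactly tile the tooth zone (10–88% of the margin
arclength), so the ground-truth sinus — the bump support edge — is also the
curvature minimum of the final outline, making truth and measurement
definitions like-for-like. Ground-truth tooth height uses the same
apex-to-sinus-chord construction as the detector; because the sinus chord
subtends a curved outline, truth heights exceed the raw bump amplitude by the
chord sagitta, intentionally mirroring what any chord-based measurement
reports.

Boundary noise is a band-limited random Fourier displacement (harmonics 1–10
along the closed contour) applied along a smoothed normal field, normalized
to the requested RMS amplitude. Smooth noise preserves contour simplicity at
the amplitudes studied (0.5% of blade length); displacement amplitudes
approaching the petiole cap radius fold the outline and are rejected.

Cohorts draw blade lengths uniformly over a range and scale blade width,
petiole dimensions and noise amplitude isometrically, so proportions and
relative noise are stage-invariant; `tooth_height_frac` is multiplied by the
genotype scale factor and a per-leaf lognormal jitter (sd 0.08 on the log
scale) emulating biological variability. What the generator does **not**
emulate: asymmetric or nested (second-order) serration, allometric shape
change along the series, venation, segmentation artifacts of real
silhouettes, or 3-D effects. Benchmarks passing on these leaves show the
measurement chain is correct and well-conditioned, not that thresholds are
tuned for any particular microscope or species.

## Contour extraction and curvature

Masks are validated (exactly one 8-connected component, not touching the
border), holes filled, then lightly Gaussian-smoothed (σ = 1 px) before
tracing the 0.5 iso-level with marching squares. Pre-smoothing puts the level
set on the true edge irrespective of edge orientation, removing the staircase
perimeter bias of tracing a binary image directly; the cost is corner rounding
at the 1-px scale. Raster coordinates map to physical ones as
`x = col·pixel_size`, `y = (H − row)·pixel_size`, keeping counter-clockwise
orientation equal to positive shoelace area. Structures narrower than ~3 px
are not reliably traced.

Curvature comes from the derivative of the periodically smoothed tangent
angle on a uniformly resampled contour: the 2π winding ramp is removed, the
periodic residual Gaussian-smoothed, and central differences applied — so the
turning-number identity ∮κ ds = 2π holds exactly by construction. The general
curvature-profile default smoothing is perimeter/200; landmark detection uses
perimeter/500 because extremum *positions* shift with the smoothing scale,
and at perimeter/200 that shift biases tooth heights by ≈ 6% (vs ≈ 2% at the
lighter setting).

## Landmark detection

Base: candidate neck points are curvature minima comparable in depth to the
deepest concavity (within 30%), with an absolute guard (2× median |κ|)
rejecting noise dips on convex outlines; among candidate pairs closer than
25% of the maximal width, the *deepest* pair (not the narrowest) is chosen —
a tapering petiole, e.g. on a mean silhouette, is narrowest at its tip, not
at the junction. The base is the pair midpoint. Without a neck, the base is
the principal-axis extreme on the wide (basal) side, using the sign of the
projection skewness. Apex: the vertex farthest from the base along the
principal axis. Near-circular shapes (principal-axis eigenvalue ratio
< 1.05²) are rejected as unorientable.

Tooth apices are curvature maxima on each margin side between base and apex
(1.5% of the contour excluded at each end; the leaf apex and petiole are
never counted), with two configurable filters: curvature prominence ≥ 0.6×
the median |κ| of the contour, and height ≥ 1% of blade length. The
prominence default was set from the measured separation on the study
conditions: genuine teeth score ≥ 1.0× median |κ| (scaled smooth-margin
genotype) and ≥ 2.1× (default teeth), while spurious peaks on toothed leaves
stay below 0.2×; 0.6 sits in the gap with ≥ 3× margin on either side. On
smooth leaves with boundary noise, prominence alone cannot reject noise
undulations (they dominate the tiny median |κ| of a featureless outline) —
there the minimum-height filter is the effective guard. The "first tooth" is
the most basal one on each side (`rank_from_base = 1`).

## Mean silhouettes

Each contour is resampled to a fixed number of points starting at its base
end and rigidly aligned — base translated to the origin, base→apex axis
rotated to vertical, never rescaled, so genotype size differences survive
averaging. For exact correspondence across leaves (and exact bilateral
symmetry for mirror pairs), every alignment step is reflection-equivariant on
the vertex set: junctions are refined to the sharpest concave corners of the
original polygon, the axis comes from PCA of the original vertices, and the
traversal starts at the exactly interpolated lowest crossing of the aligned
contour with its own axis (the petiole tip). The mean of a leaf and its
mirror image is then bilaterally symmetric to floating-point precision, and
the mean silhouette's blade length matches the arithmetic mean of the input
blade lengths to well under 1%.

## Trajectories and tests

LOESS uses tricube weights over the span-fraction nearest neighbours
(defaults: degree 1, span 0.75), fitted by centred weighted least squares and
evaluated at each grid node; nodes with fewer than degree+2 usable points are
flagged NaN, never extrapolated. Degree-1 fits reproduce exactly linear data
to machine precision, and the implementation is cross-checked against
statsmodels' lowess in the test suite.

Between-genotype tests are equal-variance Student's t-tests within half-open
blade-length classes `[e_i, e_{i+1})`, defaults 200–400–600–800 µm; Welch's
correction is available behind a flag, and no multiple-testing correction is
applied across the three classes by default. Classes with fewer than two
points in either group are reported untestable rather than dropped. Label
permutation on signal-free cohorts calibrates the p < 0.005 level: the
empirical false-positive rate is ≈ 0.005 within binomial error (2000
permutations × 3 classes).

## Reporter quantification

Background: median and 1.4826×MAD of an annulus around the seed (defaults
r_in = 1.5×, r_out = 3× the expected zone radius). The median is exactly
immune to ≤ 50% saturating outliers on a flat background; with continuous
noise, 10% contamination shifts it by up to ≈ 0.14σ — robust, but not
unchanged. Zone: 8-connected component above `background + k·spread`
(default k = 3) containing the seed; an empty mask when the seed is below
threshold. Accumulated intensity sums background-subtracted zone pixels with
negative terms clipped (zone pixels exceed the threshold by construction, so
clipping only guards edge cases); a `raw_sum` option skips subtraction.
Because the background is re-estimated per image, the readout is invariant to
global intensity offsets, and it recovers the generator's zone signal within
a few percent at SNR 5 and is linear in zone amplitude (R² > 0.99).

Nuclei: difference-of-Gaussians bandpass (σ vs 1.6σ) local maxima with a
minimum separation, each measured as the mean raw intensity in a disk of
radius 2σ; the reporter statistic is the mean of the 12 most intense nuclei,
flagged when fewer than 12 are present. The caller supplies the 2-D plane;
no z-selection is performed.

## Problem sizes

The validation studies run at: 100 leaves for landmark recovery, two matched
cohorts of 50 leaves (tooth-height scale 1.0 vs 0.5, blade range 200–800 µm)
for the discrimination study, 2000 label permutations for calibration,
160–256 px synthetic images for reporter recovery, and 1024-point contours
for hull and landmark work — sizes at which every reported rate is stable to
the few-percent level across seeds.

## Known limitations

* The auto-alpha heuristic assumes elongated blades; near-circular outlines
  need an explicit alpha (see above).
* Neck detection assumes the petiole is the narrowest deep-concave passage;
  exotic shapes with deep narrow sinuses closer than the petiole width could
  confuse it.
* Tooth detection reports first-order serration only; nested teeth merge
  into their parents.
* Contour extraction expects solid, already-binary silhouettes — no raw-image
  segmentation is attempted.
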
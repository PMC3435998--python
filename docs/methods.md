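# Methods

This note documents the models, parameters and numerical choices behind
peachvision, and what the synthetic test bed does and does not establish
about real orchard images.

## Pixel classification by linear color models

An object's pixels under varying illumination trace an approximately linear
trajectory in the RGB cube: illumination scales the three channels jointly,
so shading moves a color along a ray rather than around a blob. Each
object/illumination condition is a *linear color model* — a line
`c + t·d` in normalized RGB (8-bit values divided by 255, so the saturated
bright-sun regime sits on the cube face `R = 1`) with a semantic class
(Peach, Leaf, Branch). One physical object may need several models (e.g. a
sunlit and a shaded peach line).

Lines are fit by **orthogonal (total) least squares**: centroid = sample
mean, direction = principal axis of the centered cloud via SVD. This is the
deliberate choice over a coordinate regression of G, B on R: it is symmetric
in the three channels and minimizes exactly the point-to-line distance used
later for classification. Directions are sign-canonicalized (first nonzero
component ≥ 0) so model files are byte-reproducible. Fits with fewer than
two distinct samples raise a degeneracy error naming the offending label.

Classification assigns each pixel to the model of minimum Euclidean
point-to-line distance, measured to the **infinite** line — the decision
surfaces are then the equidistant surfaces between lines and no extra
thresholds are needed. Ties break to the earliest model in the set, which
makes the label map deterministic and user-controllable via model order.
Model sets must contain at least one Peach model; there is deliberately no
canned "standard" model set, because useful lines depend on the camera and
illumination and must be fit from annotated regions of representative
images (annotation rectangles are 0-based, half-open `(row0, col0, row1,
col1)`).

## Mask construction

Pixels classified to any Peach-class model form the fruit mask. Cleanup:

* 8-connected foreground components with **fewer than `min_size = 50`**
  pixels are removed (a 50-pixel component survives — the inequality is
  strict, and the size filter is implemented directly on component pixel
  counts to pin that semantics);
* background regions not 4-connected to the image border (enclosed holes)
  are filled.

The 8/4 connectivity pair for foreground/background is the standard
complementary choice that avoids topological paradoxes. Cleanup is
idempotent, never removes a pixel of a surviving component, and adds only
hole pixels.

## Diameter estimation

Per fruit blob, the contour is the set of foreground pixels with a
4-neighbor outside the mask (border pixels included), in row-major order.
Two measurements follow.

**MD** — the maximum pairwise distance between contour pixels. For contours
above 400 points the maximum is computed on the convex hull vertices, which
is exact (the diameter of a point set is attained between hull vertices);
degenerate collinear input falls back to the full pairwise scan.

**Focal-form ellipse fit.** The flattened paraguayo silhouette is modeled
as an ellipse parameterized by its two foci and major axis length (the
"string construction"), with per-point residual

```
r_i = d(p_i, f1) + d(p_i, f2) − 2a .
```

The reported `relative_residuals` are `|r_i| / a` — residuals in units of
the fitted *semi-major axis*. This normalization is size-invariant across
image resolutions and puts the canonical defect geometry well clear of the
rejection threshold: a straight chord replacing a quarter of a circle's arc
has sagitta `0.293·a`, producing relative residuals ≈ 0.3–0.6 against a
clean-contour background of ≤ 0.04, so the 0.15 threshold separates the two
with a wide margin. (Normalizing by the full axis `2a` instead would park
that same chord right at the threshold and make rejection a coin flip.)

Numerical design of the fit:

* **Parameterization and bounds.** Internally the solver works in
  `(center, θ, eccentricity, 2a)`. The raw focal parameterization has a
  degenerate valley — both foci receding to infinity with `2a` tracking
  `|f1 − f2|` flattens the ellipse into an infinite segment on which every
  residual vanishes, and this valley is downhill-connected even from the
  true solution for occluded contours. Physical bounds close it: the center
  stays in the contour's bounding box, eccentricity ≤ 0.95, and
  `2a ≤ 2·MD`. Foci and `2a` remain the reported interface; θ is periodic
  and left unbounded.
* **Initialization.** Moments of the point cloud: centroid, principal-axis
  angle, an eccentricity estimate from the major/minor spreads, `2a = MD`.
  Starting both foci at the centroid is a trap — the objective is symmetric
  in the foci, so every descent step moves them identically and the fit can
  never leave the circle subspace; the moment-based eccentricity breaks the
  symmetry.
* **Robust loss, graduated.** Residuals are aggregated with a redescending
  `arctan` loss (`f_scale = 1` px): a coherent contour defect such as a
  leaf's edge then cannot drag the consensus fit, and instead surfaces at
  full strength in the residuals where the rejection threshold catches it.
  A plain squared loss would split the difference — absorbing roughly half
  the defect into the fit and leaving residuals just *below* the threshold,
  so nothing would ever be rejected. Because redescending losses have
  spurious minima (e.g. treating the far half of the contour as outliers),
  the solver runs graduated non-convexity: a plain least-squares pass and a
  `soft_l1 → cauchy` ladder provide two starting points for the final
  `arctan` refinement, and the candidate with the lower robust cost wins.
  All stages use `scipy.optimize.least_squares` (TRF, analytic Jacobian,
  tolerances 1e-14).

**Two-stage fit.** F1 fits all contour points; indices with relative
residual > `residual_threshold` (default **0.15**) are rejected; F2 refits
the retained points starting from F1's optimum. If rejection would leave
fewer than the 5 points needed to determine the 5 parameters, F2 falls back
to F1 and nothing is rejected.

**Occlusion classes.** With `similarity_tol = 0.05`:
`|MAL-F2 − MAL-F1| ≤ 0.05·MAL-F1` → `non_occluded` (either value usable;
the refined F2 is reported as the recommended diameter);
`F2 > F1` → `occluded_le_33` (F2 discarded, F1 recommended);
`F2 < F1` → `occluded_gt_66` (no recommended diameter). Only these three
classes exist: the 33–66% band is not distinguishable by this rule. A
caveat from our synthetic experiments: on clean single-fruit masks with one
smooth occluding lobe, the robust F1 and the post-rejection F2 agree
closely at *any* occlusion level, so the rule reliably reports
`non_occluded` and rarely fires the two occluded classes. The occluded
signatures appear to require the ragged, fragment-merging segmentation
errors of real imagery rather than clean geometric occlusion; treat the
class output as a coarse flag, and prefer MD-vs-MAL disagreement and
`n_rejected` as additional occlusion evidence. MD monotonicity (occlusion
can only shrink MD) holds exactly by construction.

Distances are in pixel units throughout; conversion to millimeters needs
external range information (LIDAR, stereo, multi-view) and is out of scope.

## Evaluation metrics

Segmentation accuracy is the symmetric-difference pixel count between
automatic and reference masks as a percentage of the **reference** fruit
area — per-fruit percentages only make sense relative to fruit size, and
the reference area is the stable normalizer. Diameter accuracy is the
percent error of MD, MAL-F1 and MAL-F2 against the MD of the reference
mask. Per condition (illumination or occlusion band) only minimum, average
and maximum are reported; the per-fruit errors follow no common
distribution, so moments beyond these are not meaningful. Manual fruit
labeling itself is only repeatable to about 3% of fruit area; comparisons
below that floor are noise. Reference masks for occluded fruit must already
encode the intended comparison (e.g. visible part only); the metrics do not
subtract occluders.

## Synthetic scenes

The generator renders what the pipeline needs to be tested against, with
exact ground truth:

* **Colors** per class are drawn from generating lines (defaults: a red
  peach line from dark shaded red to bright saturated red-orange, a
  green-dominant leaf line, a dim brown branch line) with per-pixel
  Gaussian noise `σ = 0.01` and clipping to the cube — the clipped peach
  colors reproduce the saturated bright-sun regime.
* **Background** is a grid of 16-px cells, each a leaf (80%) or branch
  (20%) with its own illumination parameter `t`: locally coherent like
  foliage, so misclassified background can form connected clumps and the
  50-px filter is actually exercised (i.i.d. pixel noise would make cleanup
  trivial).
* **Fruits** are rasterized ellipses with semi-major axis 28–42 px,
  flattening (minor/major) 0.70–0.80 around the paraguayo's ~0.75, random
  orientation, and a radial shading gradient (bright center, darker rim)
  along the peach line.
* **Occluders** are leaf-colored lobes grown pixel-by-pixel from a random
  fruit-boundary seed in jittered distance order — compact and smooth-edged
  like a leaf — stopping the first time coverage reaches the target
  fraction, so the achieved fraction is exact to one pixel.
* Scenes are bit-identical for a given seed; the ground truth includes
  ready-made pure-class annotation rectangles so the full
  annotate→fit→classify loop can run without a human.

What passing on this test bed shows: the geometry and classification
machinery are correct to their stated tolerances under the stated noise.
What it does not show: robustness to out-of-model colors (sky, soil, unripe
green fruit), camera effects (blur, chromatic noise, exposure changes),
touching/overlapping fruit (out of scope by assumption), or the ragged
segmentation edges of real images — the default scenes are nearly separable
in color space, so end-to-end agreement near 100% is expected there, not
impressive.

## Default parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `min_size` | 50 | px | components smaller than this are deleted |
| `residual_threshold` | 0.15 | ×a | rejection level for the second fit |
| `similarity_tol` | 0.05 | — | relative MAL gap treated as "similar" |
| `max_eccentricity` | 0.95 | — | bound on the fitted ellipse |
| noise `σ` | 0.01 | normalized RGB | generator sensor noise |
| flattening | 0.70–0.80 | — | generator fruit minor/major ratio |
| cell size | 16 | px | generator background coherence scale |

## Known limitations

* One fruit per blob: overlapping fruit sharing one component are measured
  as a single object.
* The occlusion-range rule is a weak signal on clean masks (see above).
* Color models must be re-fit per camera/illumination campaign; no
  automatic model discovery is provided.
* Sub-pixel rasterization bias: contour-based MD/MAL sit ~0.5–1.5 px below
  the continuous silhouette's diameter.
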
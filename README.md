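# peachvision

Detection and sizing of red peaches in orchard images, built for the flat
(*Prunus persica* var. *platycarpa*, "paraguayo") red-skinned variety
photographed under natural light. It is aimed at agricultural machine-vision
work — yield estimation, harvest planning, robotic picking — where fruit must
be found and measured in RGB photographs full of leaves, branches and harsh
illumination changes.

## The method

**Linear color models.** Under varying illumination the pixels of one object
(peach skin, a leaf, a branch) do not form a blob in RGB space — they slide
along a line, because light intensity scales all three channels together.
Each object/illumination condition is therefore modeled as a 3-D line in the
normalized RGB cube,

```
L = { c + t·d : t ∈ ℝ },   c = centroid,  ‖d‖ = 1,
```

fit to hand-annotated sample pixels by total least squares (the principal
axis of the centered sample cloud). A pixel `p` is classified to the model of
smallest point-to-line distance

```
dist(p, L) = ‖(p − c) − ((p − c)·d) d‖ ,
```

with no extra thresholds: the decision surfaces are equidistant between
lines. Pixels whose winning model carries the *Peach* class form a binary
mask; 8-connected components under 50 px are discarded and enclosed holes
filled.

**Sizing.** Each fruit blob's contour is measured two ways:

* `MD` — maximum pairwise distance between contour pixels (exact for a free
  fruit, biased low under occlusion);
* `MAL` — major axis length `2a` of an ellipse in *focal form* (two foci and
  the constant focal-distance sum), fit by robust nonlinear least squares on
  the residuals `d(p, f₁) + d(p, f₂) − 2a`. A first fit (F1) uses all
  contour pixels; pixels whose residual exceeds 0.15 (in units of the fitted
  semi-major axis) are rejected and a second fit (F2) refits the rest.

Comparing the two fits gives a coarse occlusion range: `MAL-F1 ≈ MAL-F2`
means the fruit is unoccluded; `F2 > F1` signals occlusion up to ~33% (use
F1); `F2 < F1` signals occlusion above ~66% (no reliable diameter).

A synthetic-scene generator with exact ground truth (fruit masks, true foci
and `2a`, achieved occlusion fractions, per-pixel classes) makes the whole
pipeline testable end to end; see `docs/methods.md` for what it does and
does not emulate.

## Worked example

Generate a scene, fit color models from its annotated patches, segment, and
measure every fruit:

```sh
peachvision synth --seed 7 --out scene
peachvision fit-models scene/image.png annotations.json --out models.json
peachvision segment scene/image.png models.json --out mask.png
peachvision measure mask.png --out measure.json
```

(`annotations.json` lists sample rectangles per object — the scene bundle's
ground truth includes ready-made ones.) The measurement report contains one
record per fruit blob; for the scene above:

```json
{
  "md": 69.72,
  "mal_f1": 69.36,
  "mal_f2": 69.36,
  "n_rejected": 0,
  "occlusion_class": "non_occluded",
  "recommended_diameter": 69.36
}
```

`md` and `mal_f1` agree within a pixel and nothing was rejected, so the blob
is an unoccluded fruit roughly 69 px across — against a generator truth of
70.2 px for that fruit (rasterization trims a sub-pixel rim, so contour
measures sit slightly under the continuous truth). Pixel units convert to
millimeters only with a camera-to-fruit distance, which is outside this
package's scope.

The same steps run from Python via `peachvision.generate_scene`,
`fit_models_from_image`, `segment_image`, `extract_components` and
`estimate_diameter`.

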
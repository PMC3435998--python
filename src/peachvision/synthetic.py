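"""Synthetic orchard scenes with exact ground truth.

Real orchard photographs of red paraguayo peaches are hard to label and
impossible to re-stage, so every stage of the pipeline is exercised on
generated scenes whose ground truth is known by construction:

* Pixel colors of each object class are drawn from a 3-D line in RGB space
  (``centroid + t * direction`` plus Gaussian noise, clipped to the unit
  cube), mirroring how illumination changes slide an object's color along a
  linear trajectory.  Pushing the peach line's ``t`` past the cube face
  emulates the saturated bright-sun appearance (a projection onto the
  ``R = 1`` plane).
* The background is a grid of locally coherent leaf/branch cells, each with
  its own illumination parameter ``t`` — regionally smooth, like foliage,
  rather than i.i.d. pixel noise.
* Fruits are rasterized flattened ellipses (default minor/major ratio about
  0.75, the paraguayo's silhouette) with a radial shading gradient, at
  random orientation.
* Occluders are leaf-colored connected blobs grown from a random point on
  the fruit boundary until they cover a target fraction of the fruit, so
  occlusion stresses both the classifier and the geometry.

The ground truth records full and visible per-fruit masks, true foci and
major axis length, achieved occlusion fractions, the per-pixel class map,
and ready-made pure-class region annotations for fitting color models.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .color_models import CLASS_NAMES, RegionAnnotation
from .fruit_geometry import extract_contour

#: per-pixel class codes, indexing into CLASS_NAMES
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}

__all__ = [
    "CLASS_CODES",
    "ColorLine",
    "default_palette",
    "sample_line_color",
    "SceneConfig",
    "FruitTruth",
    "SceneGroundTruth",
    "generate_scene",
    "occlude_fruit",
    "rasterize_ellipse",
    "save_scene_bundle",
]


@dataclass(frozen=True)
class ColorLine:
    """Generating color line: centroid + t * direction, with noise sigma."""

    centroid: tuple[float, float, float]
    direction: tuple[float, float, float]
    t_range: tuple[float, float]
    sigma: float = 0.01

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm == 0:
            raise ValueError("direction must be nonzero")
        object.__setattr__(self, "direction", tuple(float(x) for x in d / norm))
        object.__setattr__(self, "centroid",
                           tuple(float(x) for x in self.centroid))
        object.__setattr__(self, "t_range",
                           tuple(float(x) for x in self.t_range))
        object.__setattr__(self, "sigma", float(self.sigma))
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def centroid_arr(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)

    @property
    def direction_arr(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.centroid_arr + t[..., None] * self.direction_arr


def default_palette() -> dict[str, ColorLine]:
    """Generating lines for ripe red peach skin, sunlit leaves and branches.

    The peach line runs from dark shaded red toward bright sun-saturated
    red-orange; its upper ``t`` range slightly exceeds the cube so clipping
    reproduces the saturated appearance.  The leaf line is green-dominant,
    the branch line a dimmer brown.
    """
    return {
        "Peach": ColorLine(
            centroid=(0.70, 0.25, 0.22),
            direction=(0.72, 0.53, 0.44),
            t_range=(-0.35, 0.42),
        ),
        "Leaf": ColorLine(
            centroid=(0.35, 0.50, 0.18),
            direction=(0.55, 0.75, 0.35),
            t_range=(-0.30, 0.45),
        ),
        "Branch": ColorLine(
            centroid=(0.38, 0.30, 0.24),
            direction=(0.62, 0.52, 0.44),
            t_range=(-0.25, 0.30),
        ),
    }


def sample_line_color(
    line: ColorLine,
    t: float,
    rng: np.random.Generator | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """One color draw: centroid + t * direction + Gaussian noise, clipped."""
    sigma = line.sigma if sigma is None else sigma
    color = line.point_at(float(t))
    if sigma > 0:
        if rng is None:
            raise ValueError("an rng is required when sigma > 0")
        color = color + rng.normal(0.0, sigma, size=3)
    return np.clip(color, 0.0, 1.0)


@dataclass
class SceneConfig:
    """Parameters of a generated orchard scene.

    All sizes are pixels.  ``occlusion_targets`` gives the fraction of each
    fruit to cover (entries in [0, 1)); ``None`` means no occlusion.
    """

    height: int = 256
    width: int = 320
    n_fruits: int = 3
    semi_major_range: tuple[float, float] = (28.0, 42.0)
    flattening_range: tuple[float, float] = (0.70, 0.80)
    occlusion_targets: list[float] | None = None
    lines: dict[str, ColorLine] = field(default_factory=default_palette)
    cell_size: int = 16
    branch_fraction: float = 0.2
    saturation_clip: bool = True
    seed: int = 0


@dataclass
class FruitTruth:
    """Ground truth of one generated fruit."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # radians, orientation of the major axis in (row, col)
    focus1: tuple[float, float]
    focus2: tuple[float, float]
    major_axis_length: float  # 2a
    full_mask: np.ndarray
    visible_mask: np.ndarray
    occluder_mask: np.ndarray
    occlusion_target: float
    occlusion_achieved: float


@dataclass
class SceneGroundTruth:
    fruits: list[FruitTruth]
    class_map: np.ndarray  # int8 of CLASS_CODES
    annotations: list[RegionAnnotation]
    lines: dict[str, ColorLine]


def rasterize_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipse mask and the elliptical radius rho on its support."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    dr = rows - center[0]
    dc = cols - center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    mask = rho2 <= 1.0
    return mask, np.sqrt(np.clip(rho2, 0.0, None))


def occlude_fruit(
    full_mask: np.ndarray,
    target_fraction: float,
    rng: np.random.Generator,
    edge_jitter: float = 1.5,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Grow a connected leaf-like occluder over a fruit until coverage is reached.

    The blob grows pixel-by-pixel from a random fruit-boundary seed, each
    step annexing the frontier pixel of smallest jittered distance to the
    seed, and stops the first time the covered fraction of the fruit reaches
    ``target_fraction``.  Distance-ordered growth yields a compact, smoothly
    bounded lobe — like a leaf lying over the fruit — with ``edge_jitter``
    (px) controlling how organic the edge looks.

    Returns ``(visible_mask, achieved_fraction, occluder_mask)``.
    """
    if not 0.0 <= target_fraction < 1.0:
        raise ValueError("target fraction must be in [0, 1)")
    full = np.asarray(full_mask).astype(bool)
    area = int(full.sum())
    occluder = np.zeros_like(full)
    if target_fraction == 0.0 or area == 0:
        return full.copy(), 0.0, occluder
    h, w = full.shape
    contour = extract_contour(full)
    sr, sc = (int(v) for v in contour[rng.integers(contour.shape[0])])
    seen = np.zeros_like(full)  # in blob or in frontier
    seen[sr, sc] = True
    heap: list[tuple[float, tuple[int, int]]] = [(0.0, (sr, sc))]
    covered = 0
    while heap and covered < target_fraction * area:
        _, (r, c) = heapq.heappop(heap)
        occluder[r, c] = True
        if full[r, c]:
            covered += 1
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and not seen[nr, nc]:
                seen[nr, nc] = True
                priority = float(np.hypot(nr - sr, nc - sc))
                if edge_jitter > 0:
                    priority += rng.normal(0.0, edge_jitter)
                heapq.heappush(heap, (priority, (nr, nc)))
    visible = full & ~occluder
    return visible, covered / area, occluder


def _place_fruits(
    config: SceneConfig, rng: np.random.Generator
) -> list[tuple[float, float, float, float, float]]:
    """Sample non-overlapping (row, col, a, b, angle) tuples."""
    a_lo, a_hi = config.semi_major_range
    placed: list[tuple[float, float, float, float, float]] = []
    for _ in range(config.n_fruits):
        for _attempt in range(5000):
            a = rng.uniform(a_lo, a_hi)
            b = a * rng.uniform(*config.flattening_range)
            margin = a + 2
            if (config.height - 2 * margin <= 0) or (config.width - 2 * margin <= 0):
                raise ValueError("fruit does not fit inside the image")
            r0 = rng.uniform(margin, config.height - margin)
            c0 = rng.uniform(margin, config.width - margin)
            # generous spacing so occluder blobs cannot spill onto neighbors
            if all(
                np.hypot(r0 - pr, c0 - pc) > a + pa + 24
                for pr, pc, pa, _pb, _ang in placed
            ):
                placed.append((r0, c0, a, b, rng.uniform(0.0, np.pi)))
                break
        else:
            raise ValueError(
                "could not place all fruits without overlap; the image is too "
                "small for the requested fruit count and sizes"
            )
    return placed


def _pure_windows(
    class_map: np.ndarray,
    code: int,
    k: int,
    stride: int,
    max_windows: int,
) -> list[tuple[int, int, int, int]]:
    """Axis-aligned k x k rectangles whose pixels all carry one class code."""
    h, w = class_map.shape
    rects = []
    for r0 in range(0, h - k + 1, stride):
        for c0 in range(0, w - k + 1, stride):
            if np.all(class_map[r0 : r0 + k, c0 : c0 + k] == code):
                rects.append((r0, c0, r0 + k, c0 + k))
                if len(rects) >= max_windows:
                    return rects
    return rects


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a scene and its exact ground truth.

    Deterministic for a given ``config.seed``: the same configuration yields
    a bit-identical image and ground truth.
    """
    if config.n_fruits < 0 or config.cell_size < 1:
        raise ValueError("invalid scene configuration")
    targets = config.occlusion_targets
    if targets is None:
        targets = [0.0] * config.n_fruits
    if len(targets) != config.n_fruits:
        raise ValueError("need one occlusion target per fruit")
    if any(not (0.0 <= t < 1.0) for t in targets):
        raise ValueError("occlusion targets must be in [0, 1)")

    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = np.zeros((h, w, 3), dtype=float)
    class_map = np.zeros((h, w), dtype=np.int8)

    leaf = config.lines["Leaf"]
    branch = config.lines["Branch"]
    peach = config.lines["Peach"]

    # locally coherent background: one class + illumination t per cell
    cs = config.cell_size
    for r0 in range(0, h, cs):
        for c0 in range(0, w, cs):
            line = branch if rng.random() < config.branch_fraction else leaf
            t = rng.uniform(*line.t_range)
            img[r0 : r0 + cs, c0 : c0 + cs] = line.point_at(t)
            class_map[r0 : r0 + cs, c0 : c0 + cs] = CLASS_CODES[
                "Branch" if line is branch else "Leaf"
            ]

    fruits: list[FruitTruth] = []
    occluder_specs: list[np.ndarray] = []
    for (r0, c0, a, b, angle), target in zip(_place_fruits(config, rng), targets):
        full, rho = rasterize_ellipse((h, w), (r0, c0), a, b, angle)
        # radial shading: bright center, darker rim, along the peach line
        t_lo, t_hi = peach.t_range
        t_field = t_lo + (t_hi - t_lo) * (1.0 - rho)
        img[full] = peach.point_at(t_field[full])
        class_map[full] = CLASS_CODES["Peach"]

        visible, achieved, occluder = occlude_fruit(full, target, rng)
        occluder_specs.append(occluder)

        c_focal = np.sqrt(max(a * a - b * b, 0.0))
        axis = np.array([np.cos(angle), np.sin(angle)])
        center = np.array([r0, c0])
        f1 = center - c_focal * axis
        f2 = center + c_focal * axis
        fruits.append(
            FruitTruth(
                center=(r0, c0),
                semi_major=a,
                semi_minor=b,
                angle=angle,
                focus1=tuple(f1),
                focus2=tuple(f2),
                major_axis_length=2.0 * a,
                full_mask=full,
                visible_mask=visible,
                occluder_mask=occluder,
                occlusion_target=float(target),
                occlusion_achieved=float(achieved),
            )
        )

    # paint occluders last (leaves lying over fruit), one t per leaf blob
    for occluder in occluder_specs:
        if occluder.any():
            t = rng.uniform(*leaf.t_range)
            img[occluder] = leaf.point_at(t)
            class_map[occluder] = CLASS_CODES["Leaf"]
    if len(occluder_specs) > 1:
        union_occ = np.logical_or.reduce(occluder_specs)
        for fr in fruits:
            fr.visible_mask = fr.full_mask & ~union_occ
            fr.occlusion_achieved = 1.0 - fr.visible_mask.sum() / fr.full_mask.sum()

    # per-pixel sensor noise, then gamut handling and 8-bit quantization
    sigma_map = np.zeros((h, w, 1))
    for name, code in CLASS_CODES.items():
        if name in config.lines:
            sigma_map[class_map == code, 0] = config.lines[name].sigma
    img = img + rng.normal(0.0, 1.0, size=img.shape) * sigma_map
    if config.saturation_clip:
        img = np.clip(img, 0.0, 1.0)
    elif img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(
            "colors leave the RGB cube; enable saturation_clip or narrow t ranges"
        )
    image8 = np.round(img * 255.0).astype(np.uint8)

    annotations = []
    for short, name in (("P", "Peach"), ("L", "Leaf"), ("B", "Branch")):
        rects = _pure_windows(
            class_map, CLASS_CODES[name], k=8,
            stride=cs if name != "Peach" else 4, max_windows=6,
        )
        if len(rects) >= 1:
            annotations.append(
                RegionAnnotation(label=f"{short}1", class_name=name, rects=rects)
            )

    truth = SceneGroundTruth(
        fruits=fruits,
        class_map=class_map,
        annotations=annotations,
        lines=dict(config.lines),
    )
    return image8, truth


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_builtin(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_scene_bundle(
    out_dir: str | Path,
    image: np.ndarray,
    truth: SceneGroundTruth,
    config: SceneConfig,
) -> None:
    """Write a scene to disk: PNGs, ground-truth JSON and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "image.png", image)
    iio.imwrite(out / "class_map.png", truth.class_map.astype(np.uint8))
    gt: dict = {
        "class_codes": CLASS_CODES,
        "lines": {
            name: {
                "centroid": list(line.centroid),
                "direction": list(line.direction),
                "t_range": list(line.t_range),
                "sigma": line.sigma,
            }
            for name, line in truth.lines.items()
        },
        "fruits": [],
    }
    for i, fr in enumerate(truth.fruits):
        iio.imwrite(out / f"fruit_{i:02d}_full.png",
                    (fr.full_mask * 255).astype(np.uint8))
        iio.imwrite(out / f"fruit_{i:02d}_visible.png",
                    (fr.visible_mask * 255).astype(np.uint8))
        gt["fruits"].append(
            {
                "center": list(fr.center),
                "semi_major": fr.semi_major,
                "semi_minor": fr.semi_minor,
                "angle": fr.angle,
                "focus1": list(fr.focus1),
                "focus2": list(fr.focus2),
                "major_axis_length": fr.major_axis_length,
                "occlusion_target": fr.occlusion_target,
                "occlusion_achieved": fr.occlusion_achieved,
            }
        )
    gt["annotations"] = [
        {"label": a.label, "class": a.class_name, "rects": [list(r) for r in a.rects]}
        for a in truth.annotations
    ]
    gt = _to_builtin(gt)
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2) + "\n")
    cfg = asdict(config)
    cfg["lines"] = gt["lines"]
    (out / "config.yaml").write_text(yaml.safe_dump(_to_builtin(cfg), sort_keys=False))
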
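"""Linear color models in the RGB vector color space.

Small image regions of a single object (peach skin, leaf, branch) under
varying illumination trace out an approximately linear trajectory in the RGB
cube: illumination scales all three channels together, so the pixel cloud of
one object lies near a 3-D line.  Each such line is a *linear color model* —
a centroid plus a unit direction in normalized RGB coordinates — labeled with
a semantic class (Peach, Leaf or Branch).  Pixels are later classified by
their Euclidean distance to the nearest model line.

Lines are fit by orthogonal (total) least squares: the direction is the
principal axis of the centered sample cloud, the centroid its mean.  This is
symmetric in R, G and B and minimizes exactly the point-to-line distance used
for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

CLASS_NAMES = ("Peach", "Leaf", "Branch")

__all__ = [
    "CLASS_NAMES",
    "FitDegeneracyError",
    "LinearColorModel",
    "ColorModelSet",
    "RegionAnnotation",
    "fit_linear_color_model",
    "point_to_model_distance",
    "distances_to_line",
    "fit_models_from_image",
    "normalize_image",
    "extract_region_pixels",
    "load_annotations",
    "save_annotations",
]


class FitDegeneracyError(ValueError):
    """Raised when a line fit is degenerate (too few or identical samples)."""

    def __init__(self, label: str, reason: str):
        self.label = label
        super().__init__(f"degenerate color-model fit for {label!r}: {reason}")


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Unit direction with the first component of magnitude > 1e-12 nonnegative."""
    d = np.asarray(d, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise ValueError("zero direction vector")
    d = d / norm
    for comp in d:
        if abs(comp) > 1e-12:
            if comp < 0:
                d = -d
            break
    return d


@dataclass(frozen=True)
class LinearColorModel:
    """A labeled 3-D line in normalized RGB space.

    Parameters
    ----------
    label : str
        Short identifier, e.g. ``"P1"``.
    class_name : str
        One of ``Peach``, ``Leaf``, ``Branch``.
    centroid : array-like of 3 floats in [0, 1]
        A point on the line (the sample mean when fitted).
    direction : array-like of 3 floats
        Unit direction of the line; sign-canonicalized so the first nonzero
        component is nonnegative.
    n_samples : int
        Number of pixels the model was fit on (>= 2).
    """

    label: str
    class_name: str
    centroid: np.ndarray
    direction: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"class_name must be one of {CLASS_NAMES}, got {self.class_name!r}"
            )
        centroid = np.asarray(self.centroid, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if centroid.shape != (3,) or direction.shape != (3,):
            raise ValueError("centroid and direction must be 3-vectors")
        if np.any(centroid < -1e-12) or np.any(centroid > 1 + 1e-12):
            raise ValueError("centroid components must lie in [0, 1]")
        if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if int(self.n_samples) < 2:
            raise ValueError("n_samples must be >= 2")
        object.__setattr__(self, "centroid", centroid)
        object.__setattr__(self, "direction", _canonical_direction(direction))
        object.__setattr__(self, "n_samples", int(self.n_samples))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "class": self.class_name,
            "centroid": [float(x) for x in self.centroid],
            "direction": [float(x) for x in self.direction],
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearColorModel":
        return cls(
            label=d["label"],
            class_name=d["class"],
            centroid=np.asarray(d["centroid"], dtype=float),
            direction=np.asarray(d["direction"], dtype=float),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class ColorModelSet:
    """An ordered collection of linear color models.

    Order is significant: pixel classification breaks distance ties in favor
    of the earliest model.  At least one model must carry the Peach class so a
    fruit mask can be derived.
    """

    models: list[LinearColorModel]
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique")
        if not any(m.class_name == "Peach" for m in self.models):
            raise ValueError("model set must contain at least one Peach model")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> LinearColorModel:
        return self.models[i]

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    @property
    def peach_indices(self) -> np.ndarray:
        return np.array(
            [i for i, m in enumerate(self.models) if m.class_name == "Peach"],
            dtype=int,
        )

    def index_of(self, label: str) -> int:
        for i, m in enumerate(self.models):
            if m.label == label:
                return i
        raise KeyError(f"no model labeled {label!r}")

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorModelSet":
        return cls(
            models=[LinearColorModel.from_dict(m) for m in d["models"]],
            provenance=d.get("provenance", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ColorModelSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RegionAnnotation:
    """Sample rectangles designating pixels of one object for model fitting.

    Rectangles are 0-based, half-open ``(row0, col0, row1, col1)`` with
    ``row0 <= r < row1`` and ``col0 <= c < col1``.
    """

    label: str
    class_name: str
    rects: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"class_name must be one of {CLASS_NAMES}, got {self.class_name!r}"
            )
        rects = []
        for r in self.rects:
            r0, c0, r1, c1 = (int(x) for x in r)
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"empty rectangle {r!r} in annotation {self.label!r}")
            rects.append((r0, c0, r1, c1))
        self.rects = rects


def normalize_image(image: np.ndarray) -> np.ndarray:
    """8-bit RGB image -> float array of normalized intensities in [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    arr = image.astype(float)
    if arr.max(initial=0.0) > 1.0 + 1e-9 or arr.min(initial=0.0) < -1e-9:
        raise ValueError("float images must already be normalized to [0, 1]")
    return arr


def fit_linear_color_model(
    samples: Iterable[Sequence[float]] | np.ndarray,
    label: str,
    class_name: str,
) -> LinearColorModel:
    """Fit a 3-D line to color samples by total least squares.

    The centroid is the componentwise mean; the direction is the principal
    axis of the centered cloud, i.e. the direction minimizing the summed
    squared *orthogonal* distances of the samples to the line.

    Raises
    ------
    FitDegeneracyError
        If fewer than two samples are given or all samples are identical.
    """
    X = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                   dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"samples must be an (n, 3) array, got shape {X.shape}")
    n = X.shape[0]
    if n < 2:
        raise FitDegeneracyError(label, f"need >= 2 samples, got {n}")
    centroid = X.mean(axis=0)
    centered = X - centroid
    # principal axis via SVD of the centered cloud
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise FitDegeneracyError(label, "all samples identical")
    return LinearColorModel(
        label=label,
        class_name=class_name,
        centroid=np.clip(centroid, 0.0, 1.0),
        direction=_canonical_direction(vt[0]),
        n_samples=n,
    )


def distances_to_line(
    points: np.ndarray, centroid: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Euclidean distances from points (n, 3) to the infinite line."""
    diff = np.asarray(points, dtype=float) - centroid
    t = diff @ direction
    resid = diff - t[..., None] * direction
    return np.sqrt(np.sum(resid * resid, axis=-1))


def point_to_model_distance(p: Sequence[float], model: LinearColorModel) -> float:
    """Euclidean distance from a color point to a model's infinite line."""
    return float(distances_to_line(np.asarray(p, dtype=float)[None, :],
                                   model.centroid, model.direction)[0])


def extract_region_pixels(image: np.ndarray, annotation: RegionAnnotation) -> np.ndarray:
    """Normalized colors (n, 3) of all pixels in the annotation's rectangles."""
    arr = normalize_image(image)
    h, w = arr.shape[:2]
    chunks = []
    for r0, c0, r1, c1 in annotation.rects:
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(
                f"rectangle {(r0, c0, r1, c1)} of annotation "
                f"{annotation.label!r} exceeds image bounds {h}x{w}"
            )
        chunks.append(arr[r0:r1, c0:c1].reshape(-1, 3))
    if not chunks:
        raise ValueError(f"annotation {annotation.label!r} has no rectangles")
    return np.concatenate(chunks, axis=0)


def fit_models_from_image(
    image: np.ndarray,
    annotations: Sequence[RegionAnnotation],
    provenance: str = "",
) -> ColorModelSet:
    """Fit one linear color model per annotation, in annotation order."""
    if len(annotations) == 0:
        raise ValueError("at least one region annotation is required")
    models = [
        fit_linear_color_model(extract_region_pixels(image, ann), ann.label,
                               ann.class_name)
        for ann in annotations
    ]
    return ColorModelSet(models=models, provenance=provenance)


def load_annotations(path: str | Path) -> list[RegionAnnotation]:
    raw = json.loads(Path(path).read_text())
    return [
        RegionAnnotation(
            label=e["label"],
            class_name=e["class"],
            rects=[tuple(r) for r in e["rects"]],
        )
        for e in raw
    ]


def save_annotations(annotations: Sequence[RegionAnnotation], path: str | Path) -> None:
    payload = [
        {"label": a.label, "class": a.class_name, "rects": [list(r) for r in a.rects]}
        for a in annotations
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
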
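"""Pixel classification and peach-mask extraction.

Every pixel is assigned to the linear color model whose line is nearest in
RGB space (ties break to the earliest model in the set).  Pixels whose winning
model carries the Peach class form a binary fruit mask, which is then cleaned:
8-connected components below a minimum size are discarded and enclosed
background holes are filled.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure

from .color_models import ColorModelSet, distances_to_line, normalize_image

#: minimum surviving component size, in pixels
DEFAULT_MIN_SIZE = 50

__all__ = [
    "DEFAULT_MIN_SIZE",
    "classify_image",
    "peach_mask",
    "clean_mask",
    "extract_components",
    "segment_image",
    "save_mask",
    "load_mask",
    "save_labelmap",
    "load_labelmap",
]


def classify_image(image: np.ndarray, models: ColorModelSet) -> np.ndarray:
    """Label every pixel with the index of its nearest color model.

    Returns an (H, W) integer array of model indices into ``models``.  Ties
    are broken by the lowest model index.
    """
    if len(models) == 0:
        raise ValueError("model set is empty")
    arr = normalize_image(image)
    h, w = arr.shape[:2]
    pts = arr.reshape(-1, 3)
    dists = np.empty((len(models), pts.shape[0]))
    for i, m in enumerate(models):
        dists[i] = distances_to_line(pts, m.centroid, m.direction)
    # argmin returns the first minimum -> lowest-index tie-break
    return np.argmin(dists, axis=0).reshape(h, w)


def peach_mask(labelmap: np.ndarray, models: ColorModelSet) -> np.ndarray:
    """Binary mask: True where the assigned model's class is Peach."""
    labelmap = np.asarray(labelmap)
    if labelmap.size and (labelmap.min() < 0 or labelmap.max() >= len(models)):
        raise ValueError("labelmap contains indices outside the model set")
    is_peach = np.array([m.class_name == "Peach" for m in models], dtype=bool)
    return is_peach[labelmap]


def clean_mask(mask: np.ndarray, min_size: int = DEFAULT_MIN_SIZE) -> np.ndarray:
    """Remove small components and fill enclosed holes.

    8-connected foreground components with strictly fewer than ``min_size``
    pixels are deleted (a component of exactly ``min_size`` pixels survives);
    background regions not 4-connected to the image border are filled.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask.copy()
    labeled = measure.label(mask, connectivity=2)
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_size  # strict <: a component of exactly min_size survives
    keep[0] = False
    cleaned = keep[labeled]
    # default cross-shaped structure = 4-connected background
    return ndimage.binary_fill_holes(cleaned)


def extract_components(mask: np.ndarray) -> list[np.ndarray]:
    """Split a binary mask into per-fruit masks.

    One boolean mask per 8-connected component, ordered by the row-major
    position of each component's first (top-left-most) pixel.
    """
    mask = np.asarray(mask).astype(bool)
    labeled = measure.label(mask, connectivity=2)
    flat = labeled.ravel()
    values, first = np.unique(flat, return_index=True)
    keep = values != 0
    order = values[keep][np.argsort(first[keep])]
    return [labeled == lab for lab in order]


def segment_image(
    image: np.ndarray,
    models: ColorModelSet,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Full segmentation: classify, binarize on Peach classes, clean.

    Returns ``(labelmap, cleaned_mask)``.
    """
    labelmap = classify_image(image, models)
    return labelmap, clean_mask(peach_mask(labelmap, models), min_size=min_size)


# ---------------------------------------------------------------------------
# file I/O: masks as single-channel 8-bit PNG (0 background / 255 foreground),
# label maps as index PNG plus a JSON sidecar mapping index -> label/class
# ---------------------------------------------------------------------------

def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_labelmap(labelmap: np.ndarray, models: ColorModelSet,
                  png_path: str | Path) -> None:
    if len(models) > 255:
        raise ValueError("more than 255 models cannot be stored in an 8-bit PNG")
    png_path = Path(png_path)
    iio.imwrite(png_path, np.asarray(labelmap).astype(np.uint8))
    sidecar = {
        str(i): {"label": m.label, "class": m.class_name}
        for i, m in enumerate(models)
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_labelmap(png_path: str | Path) -> tuple[np.ndarray, dict]:
    png_path = Path(png_path)
    labelmap = iio.imread(png_path).astype(int)
    sidecar = json.loads(png_path.with_suffix(".json").read_text())
    return labelmap, sidecar
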
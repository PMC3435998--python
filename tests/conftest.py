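"""Shared generators for geometric and color fixtures."""

from __future__ import annotations

import numpy as np
import pytest


def ellipse_points(
    a: float,
    b: float,
    center=(100.0, 100.0),
    angle: float = 0.0,
    n: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Points sampled exactly on an ellipse boundary, as (row, col).

    With an rng, parameter angles are drawn uniformly; otherwise they are
    equally spaced.
    """
    if rng is None:
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    else:
        t = rng.uniform(0.0, 2.0 * np.pi, n)
    x = a * np.cos(t)
    y = b * np.sin(t)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return (rot @ np.vstack([x, y])).T + np.asarray(center, dtype=float)


def chord_bitten_ellipse(
    rng: np.random.Generator,
    n: int = 100,
    bite_arc_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, float]:
    """An ellipse contour whose bitten arc is replaced by its straight chord.

    Returns ``(points, is_chord_mask, true_major_axis_length)``.
    """
    a = rng.uniform(40.0, 60.0)
    b = a * rng.uniform(0.72, 0.9)
    angle = rng.uniform(0.0, np.pi)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rel = (t - phi0) % (2.0 * np.pi)
    in_bite = rel <= bite_arc_fraction * 2.0 * np.pi
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    pts = (rot @ np.vstack([a * np.cos(t), b * np.sin(t)])).T + 100.0
    order = np.nonzero(in_bite)[0][np.argsort(rel[in_bite])]
    chord = np.linspace(pts[order[0]], pts[order[-1]], order.size)
    out = np.vstack([pts[~in_bite], chord])
    is_chord = np.zeros(out.shape[0], dtype=bool)
    is_chord[(~in_bite).sum():] = True
    return out, is_chord, 2.0 * a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
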
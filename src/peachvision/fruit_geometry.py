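"""Fruit sizing from a segmented mask.

The flat (platycarpa) paraguayo peach projects to a flattened, roughly
elliptical silhouette, so its apparent diameter is measured two ways:

* **MD** — the maximum pairwise Euclidean distance between contour pixels.
  Exact for an unoccluded fruit, but it shrinks as soon as leaves cover part
  of the silhouette.
* **MAL** — the major axis length ``2a`` of an ellipse fit to the contour in
  *focal form*: two foci ``f1, f2`` and the constant focal-distance sum
  ``2a``, with per-point residual ``d(p, f1) + d(p, f2) - 2a``.  A first fit
  (F1) uses every contour pixel; points whose residual exceeds a threshold
  (default 0.15 in units of the fitted semi-major axis) are rejected and a
  second fit (F2) is run on the retained points.

Comparing MAL-F1 with MAL-F2 gives a coarse occlusion range: similar values
mean the fruit is essentially unoccluded (either is a usable diameter); F2
longer than F1 indicates occlusion up to roughly a third of the fruit, and
only the first fit should be trusted; F2 *shorter* than F1 indicates that
most of the silhouette is gone (occlusion above about two thirds) and no
diameter estimate is reliable.

Fitting notes.  The focal parameterization has a degenerate valley: letting
both foci recede to infinity with ``2a`` tracking ``|f1 - f2|`` flattens the
ellipse into an infinite segment on which every residual vanishes, so the
optimization is bounded by physical priors — the center stays inside the
contour's bounding box, ``2a`` below twice the maximum pairwise distance,
and the eccentricity below 0.95.  The residuals are aggregated with a
redescending (arctan) robust loss so that a coherent contour defect — a
leaf's edge biting into the silhouette — does not drag the consensus fit and
instead shows up at full strength in the residuals, where the rejection
threshold can catch it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

DEFAULT_RESIDUAL_THRESHOLD = 0.15
DEFAULT_SIMILARITY_TOL = 0.05
DEFAULT_MAX_ECCENTRICITY = 0.95

OCCLUSION_CLASSES = ("non_occluded", "occluded_le_33", "occluded_gt_66")

__all__ = [
    "DEFAULT_RESIDUAL_THRESHOLD",
    "DEFAULT_SIMILARITY_TOL",
    "DEFAULT_MAX_ECCENTRICITY",
    "OCCLUSION_CLASSES",
    "EllipseFit",
    "DiameterEstimate",
    "extract_contour",
    "max_pairwise_distance",
    "fit_ellipse_focal",
    "two_stage_fit",
    "classify_occlusion",
    "estimate_diameter",
]


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask, as an (n, 2) array of (row, col).

    A foreground pixel belongs to the contour if at least one of its
    4-neighbors is background, or it lies on the image border.  Points are
    returned in row-major order.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract a contour from an empty mask")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    rows, cols = np.nonzero(boundary)
    return np.column_stack([rows, cols])


def max_pairwise_distance(points: np.ndarray) -> float:
    """Maximum Euclidean distance over all point pairs (the diameter proxy MD)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] > 400:
        # the maximum is attained between convex-hull vertices
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear input: fall through to the full pairwise scan
    return float(pdist(pts).max())


@dataclass
class EllipseFit:
    """Result of a focal-form ellipse fit.

    ``per_point_residuals[i]`` is the signed quantity
    ``d(p_i, focus1) + d(p_i, focus2) - major_axis_length``;
    ``relative_residuals`` are their magnitudes in units of the fitted
    semi-major axis (``major_axis_length / 2``), making the rejection
    threshold size-invariant.
    """

    focus1: np.ndarray
    focus2: np.ndarray
    major_axis_length: float
    per_point_residuals: np.ndarray
    relative_residuals: np.ndarray
    converged: bool

    @property
    def center(self) -> np.ndarray:
        return (self.focus1 + self.focus2) / 2.0

    @property
    def focal_distance(self) -> float:
        return float(np.linalg.norm(self.focus1 - self.focus2))


# internal parameter vector: (center_row, center_col, theta, eccentricity, 2a)

def _foci_from_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cr, cc, theta, ecc, length = x
    c = 0.5 * length * ecc
    u = np.array([np.cos(theta), np.sin(theta)])
    center = np.array([cr, cc])
    return center - c * u, center + c * u


def _residuals(x: np.ndarray, pts: np.ndarray) -> np.ndarray:
    f1, f2 = _foci_from_params(x)
    d1 = np.linalg.norm(pts - f1, axis=1)
    d2 = np.linalg.norm(pts - f2, axis=1)
    return d1 + d2 - x[4]


def _jacobian(x: np.ndarray, pts: np.ndarray) -> np.ndarray:
    _, _, theta, ecc, length = x
    f1, f2 = _foci_from_params(x)
    v1 = pts - f1
    v2 = pts - f2
    d1 = np.maximum(np.linalg.norm(v1, axis=1), 1e-12)
    d2 = np.maximum(np.linalg.norm(v2, axis=1), 1e-12)
    g1 = -v1 / d1[:, None]  # d res / d f1
    g2 = -v2 / d2[:, None]
    u = np.array([np.cos(theta), np.sin(theta)])
    du = np.array([-np.sin(theta), np.cos(theta)])
    c = 0.5 * length * ecc
    diff = g2 - g1  # foci move oppositely along u
    jac = np.empty((pts.shape[0], 5))
    jac[:, 0:2] = g1 + g2
    jac[:, 2] = c * (diff @ du)
    jac[:, 3] = 0.5 * length * (diff @ u)
    jac[:, 4] = 0.5 * ecc * (diff @ u) - 1.0
    return jac


def _params_from_focal(guess: np.ndarray) -> np.ndarray:
    """Convert an external [f1_r, f1_c, f2_r, f2_c, 2a] guess to internal form."""
    f1 = np.asarray(guess[0:2], dtype=float)
    f2 = np.asarray(guess[2:4], dtype=float)
    length = float(guess[4])
    center = (f1 + f2) / 2.0
    sep = f2 - f1
    c = float(np.linalg.norm(sep)) / 2.0
    theta = float(np.arctan2(sep[1], sep[0])) if c > 1e-12 else 0.0
    ecc = 2.0 * c / length if length > 0 else 0.0
    return np.array([center[0], center[1], theta, ecc, length])


def _moment_init(pts: np.ndarray, md: float) -> np.ndarray:
    """Moment-based starting point.

    Starting both foci at the centroid stalls: the objective is symmetric in
    the foci, so every descent step moves them identically and the fit
    collapses to a circle.  The principal axis and the spread of the cloud
    give an eccentricity estimate that breaks the symmetry.
    """
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    theta = float(np.arctan2(vt[0, 1], vt[0, 0]))
    major = centered @ vt[0]
    minor = centered @ vt[1]
    a0 = max((major.max() - major.min()) / 2.0, 1e-6)
    b0 = max((minor.max() - minor.min()) / 2.0, 1e-6)
    ecc0 = float(np.sqrt(max(1.0 - (b0 / a0) ** 2, 0.0)))
    return np.array([centroid[0], centroid[1], theta, ecc0, md])


def fit_ellipse_focal(
    contour: np.ndarray,
    initial_guess: np.ndarray | None = None,
    max_eccentricity: float = DEFAULT_MAX_ECCENTRICITY,
) -> EllipseFit:
    """Fit an ellipse in focal form to contour points.

    Minimizes the per-point residuals ``d(p_i, f1) + d(p_i, f2) - 2a`` over
    the two foci and the major axis length, using a robust (redescending
    arctan) loss with bound constraints that keep the solution a physically
    plausible fruit silhouette (see the module docstring).

    Parameters
    ----------
    contour : (n, 2) array of (row, col) points, n >= 5.
    initial_guess : optional length-5 array ``[f1_row, f1_col, f2_row,
        f2_col, 2a]``; by default a moment-based guess from the point cloud.
    max_eccentricity : upper bound on the fitted eccentricity.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array")
    if pts.shape[0] < 5:
        raise ValueError(
            f"focal-form ellipse fit needs >= 5 points, got {pts.shape[0]}"
        )
    md = max_pairwise_distance(pts)
    if initial_guess is not None:
        x0 = _params_from_focal(np.asarray(initial_guess, dtype=float))
    else:
        x0 = _moment_init(pts, md)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    # theta is periodic, so it stays unbounded
    lower = np.array([lo[0], lo[1], -np.inf, 0.0, 1e-6])
    upper = np.array([hi[0], hi[1], np.inf, max_eccentricity, 2.0 * md])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    def refine(start, loss=None):
        kwargs = {} if loss is None else dict(loss=loss, f_scale=1.0)
        return least_squares(
            _residuals, start, jac=_jacobian, args=(pts,),
            bounds=(lower, upper), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=1000, **kwargs,
        )

    def robust_cost(params):
        return float(np.sum(np.arctan(_residuals(params, pts) ** 2)))

    # Graduated non-convexity with two start paths.  The redescending arctan
    # objective has spurious minima that treat large parts of the contour as
    # outliers, so it is only used as the last rung of a ladder of
    # progressively harder losses; a plain least-squares warm start covers
    # the clean-contour case where the ladder is unnecessary.  The candidate
    # with the lower robust cost wins.
    warm = refine(x0)
    ladder = x0
    for loss in ("soft_l1", "cauchy"):
        ladder = refine(ladder, loss).x
    candidates = [refine(warm.x, "arctan"), refine(ladder, "arctan")]
    result = min(candidates, key=lambda r: robust_cost(r.x))
    x = result.x
    f1, f2 = _foci_from_params(x)
    length = float(x[4])
    residuals = _residuals(x, pts)
    rel = np.abs(residuals) / max(0.5 * length, 1e-12)
    return EllipseFit(
        focus1=f1,
        focus2=f2,
        major_axis_length=length,
        per_point_residuals=residuals,
        relative_residuals=rel,
        converged=bool(result.success),
    )


def two_stage_fit(
    contour: np.ndarray,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
) -> tuple[EllipseFit, EllipseFit, np.ndarray]:
    """Two-pass focal fit with residual-based rejection.

    F1 fits every contour point.  Points whose relative residual in F1
    exceeds ``residual_threshold`` are rejected; F2 refits the retained
    points, initialized from F1's optimum.  If rejection would leave fewer
    than five points, F2 falls back to F1 and nothing is rejected.

    Returns ``(f1_fit, f2_fit, rejected_indices)``.
    """
    pts = np.asarray(contour, dtype=float)
    f1 = fit_ellipse_focal(pts)
    rejected = np.nonzero(f1.relative_residuals > residual_threshold)[0]
    if pts.shape[0] - rejected.size < 5 or rejected.size == 0:
        return f1, f1, np.empty(0, dtype=int)
    keep = np.setdiff1d(np.arange(pts.shape[0]), rejected)
    x0 = np.concatenate([f1.focus1, f1.focus2, [f1.major_axis_length]])
    f2 = fit_ellipse_focal(pts[keep], initial_guess=x0)
    return f1, f2, rejected


def classify_occlusion(
    mal_f1: float,
    mal_f2: float,
    similarity_tol: float = DEFAULT_SIMILARITY_TOL,
) -> str:
    """Infer the occlusion range from the two major axis lengths.

    * Similar lengths (within ``similarity_tol`` relative to F1) — the fruit
      is not occluded; either length is a usable diameter.
    * F2 longer — occlusion up to ~33%; the second fit must be discarded and
      MAL-F1 used.
    * F2 shorter — occlusion above ~66%; no diameter estimate is reliable.
    """
    if mal_f1 <= 0 or mal_f2 <= 0:
        raise ValueError("major axis lengths must be positive")
    if abs(mal_f2 - mal_f1) / mal_f1 <= similarity_tol:
        return "non_occluded"
    if mal_f2 > mal_f1:
        return "occluded_le_33"
    return "occluded_gt_66"


@dataclass
class DiameterEstimate:
    """All diameter measurements of one segmented fruit, in pixel units."""

    md: float
    mal_f1: float
    mal_f2: float
    n_rejected: int
    occlusion_class: str
    recommended_diameter: float | None

    def to_dict(self) -> dict:
        return {
            "md": self.md,
            "mal_f1": self.mal_f1,
            "mal_f2": self.mal_f2,
            "n_rejected": self.n_rejected,
            "occlusion_class": self.occlusion_class,
            "recommended_diameter": self.recommended_diameter,
        }


def estimate_diameter(
    mask: np.ndarray,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    similarity_tol: float = DEFAULT_SIMILARITY_TOL,
) -> DiameterEstimate:
    """Measure one segmented fruit: MD, MAL-F1, MAL-F2 and occlusion class.

    The mask must contain a single connected fruit blob (use
    :func:`peachvision.segmentation.extract_components` first).
    """
    contour = extract_contour(mask).astype(float)
    md = max_pairwise_distance(contour)
    f1, f2, rejected = two_stage_fit(contour, residual_threshold=residual_threshold)
    cls = classify_occlusion(f1.major_axis_length, f2.major_axis_length,
                             similarity_tol=similarity_tol)
    if cls == "non_occluded":
        recommended: float | None = f2.major_axis_length
    elif cls == "occluded_le_33":
        recommended = f1.major_axis_length
    else:
        recommended = None
    return DiameterEstimate(
        md=md,
        mal_f1=f1.major_axis_length,
        mal_f2=f2.major_axis_length,
        n_rejected=int(rejected.size),
        occlusion_class=cls,
        recommended_diameter=recommended,
    )
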
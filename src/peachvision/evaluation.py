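"""Segmentation and sizing accuracy metrics.

Automatic fruit masks are compared against reference masks (manual labels or
synthetic ground truth).  Area accuracy is the size of the symmetric
difference between the two masks as a percentage of the reference fruit
area; sizing accuracy is the relative error of MD, MAL-F1 and MAL-F2 against
the MD measured on the reference mask.  Results are reported per fruit and
summarized per condition (illumination or occlusion band) by minimum,
average and maximum, since the per-fruit errors follow no common
distribution.

Reference masks for occluded fruit should already encode the comparison the
caller wants (e.g. only the visible part of the fruit); no occluder
subtraction happens here.  Manual labeling itself carries an area
uncertainty of about 3%, which should be read as a floor under these
metrics rather than subtracted from them.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fruit_geometry import DiameterEstimate

METRIC_NAMES = (
    "pixel_diff_pct",
    "md_err_pct",
    "mal_f1_err_pct",
    "mal_f2_err_pct",
)

__all__ = [
    "METRIC_NAMES",
    "SegmentationComparison",
    "ConditionSummary",
    "pixel_difference_error",
    "relative_diameter_errors",
    "compare_fruit",
    "summarize_condition",
    "write_report",
]


@dataclass
class SegmentationComparison:
    """Per-fruit comparison between automatic and reference segmentation."""

    pixel_diff_pct: float
    reference_area: int
    auto_area: int
    md_err_pct: float = float("nan")
    mal_f1_err_pct: float = float("nan")
    mal_f2_err_pct: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "pixel_diff_pct": self.pixel_diff_pct,
            "reference_area": self.reference_area,
            "auto_area": self.auto_area,
            "md_err_pct": self.md_err_pct,
            "mal_f1_err_pct": self.mal_f1_err_pct,
            "mal_f2_err_pct": self.mal_f2_err_pct,
        }


@dataclass
class ConditionSummary:
    """Min / average / max of each metric over the fruits of one condition."""

    tag: str
    n: int
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"tag": self.tag, "n": self.n, "metrics": self.metrics}


def pixel_difference_error(auto: np.ndarray, reference: np.ndarray) -> float:
    """Symmetric-difference pixel count as a percentage of the reference area."""
    auto = np.asarray(auto).astype(bool)
    reference = np.asarray(reference).astype(bool)
    if auto.shape != reference.shape:
        raise ValueError(
            f"mask shapes differ: {auto.shape} vs {reference.shape}"
        )
    ref_area = int(reference.sum())
    if ref_area == 0:
        raise ValueError("reference mask is empty")
    return 100.0 * int(np.logical_xor(auto, reference).sum()) / ref_area


def relative_diameter_errors(
    auto_estimate: DiameterEstimate, reference_md: float
) -> tuple[float, float, float]:
    """Percent errors of (MD, MAL-F1, MAL-F2) relative to the reference MD."""
    if reference_md <= 0:
        raise ValueError("reference MD must be positive")
    def err(v: float) -> float:
        return 100.0 * abs(v - reference_md) / reference_md
    return (err(auto_estimate.md), err(auto_estimate.mal_f1),
            err(auto_estimate.mal_f2))


def compare_fruit(
    auto_mask: np.ndarray,
    reference_mask: np.ndarray,
    auto_estimate: DiameterEstimate | None = None,
    reference_md: float | None = None,
) -> SegmentationComparison:
    """Build a full per-fruit comparison record.

    Diameter errors are filled only when both an automatic estimate and a
    reference MD are supplied.
    """
    comp = SegmentationComparison(
        pixel_diff_pct=pixel_difference_error(auto_mask, reference_mask),
        reference_area=int(np.asarray(reference_mask).astype(bool).sum()),
        auto_area=int(np.asarray(auto_mask).astype(bool).sum()),
    )
    if auto_estimate is not None and reference_md is not None:
        comp.md_err_pct, comp.mal_f1_err_pct, comp.mal_f2_err_pct = (
            relative_diameter_errors(auto_estimate, reference_md)
        )
    return comp


def summarize_condition(
    comparisons: Sequence[SegmentationComparison], tag: str
) -> ConditionSummary:
    """Min / mean / max of every metric over a nonempty list of comparisons."""
    if len(comparisons) == 0:
        raise ValueError("cannot summarize an empty list of comparisons")
    metrics: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        values = np.array([getattr(c, name) for c in comparisons], dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            continue
        metrics[name] = {
            "min": float(values.min()),
            "average": float(values.mean()),
            "max": float(values.max()),
        }
    return ConditionSummary(tag=tag, n=len(comparisons), metrics=metrics)


def write_report(
    comparisons: Sequence[SegmentationComparison],
    summaries: Sequence[ConditionSummary],
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> dict:
    """Serialize per-fruit rows and per-condition summaries to JSON and/or CSV."""
    payload = {
        "fruits": [c.to_dict() for c in comparisons],
        "summaries": [s.to_dict() for s in summaries],
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fruit", "reference_area", "auto_area",
                             *METRIC_NAMES])
            for i, c in enumerate(comparisons):
                writer.writerow([
                    i, c.reference_area, c.auto_area,
                    *(getattr(c, name) for name in METRIC_NAMES),
                ])
            writer.writerow([])
            writer.writerow(["condition", "n", "metric", "min", "average", "max"])
            for s in summaries:
                for name, stats in s.metrics.items():
                    writer.writerow([s.tag, s.n, name, stats["min"],
                                     stats["average"], stats["max"]])
    return payload
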
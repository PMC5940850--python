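"""Per-segment feature export and segmentation-quality scoring.

Quality against a ground-truth label mask combines two ingredients: the
relative count deviation ``q1 = 100*|n_pred - n_gt|/n_gt`` (percent) and the
pixel misclassification fraction ``q2 = (FP + FN)/|gt foreground|`` clamped
to 1.  The combined score ``Q = (1 - min(1, q1/100)) * (1 - q2)`` lies in
[0, 1], is 1 exactly for a perfect segmentation and 0 for an empty one; the
combination rule is a swappable strategy (see ``combine``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk
from skimage.segmentation import watershed

from .core_model import Segment, SegmentationResult
from .image_prep import NormalizedImage

__all__ = [
    "QualityReport",
    "extract_features",
    "features_table",
    "quality_q",
    "quality_mean",
    "circles_to_mask",
]

FEATURE_COLUMNS = [
    "image",
    "segment_id",
    "area_px",
    "equiv_radius_px",
    "eccentricity",
    "mean_intensity",
    "centroid_row",
    "centroid_col",
]


@dataclass(frozen=True)
class QualityReport:
    """Combined quality Q plus its count (q1) and pixel (q2) ingredients."""

    Q: float
    q1: float  # count deviation, percent
    q2: float  # misclassified-pixel fraction of ground-truth mass
    n_detected: int
    n_truth: int


def extract_features(seg: Segment, img: NormalizedImage | np.ndarray | None = None) -> dict:
    """Feature record for one segment (area, radius, shape, intensity)."""
    mean_int = seg.mean_intensity
    if img is not None:
        px = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img)
        mean_int = float(px[seg.rows, seg.cols].mean())
    return {
        "area_px": seg.area,
        "equiv_radius_px": seg.equiv_radius,
        "eccentricity": seg.eccentricity,
        "mean_intensity": mean_int,
        "centroid_row": seg.centroid[0],
        "centroid_col": seg.centroid[1],
    }


def features_table(result: SegmentationResult, image_name: str = "") -> pd.DataFrame:
    """Frozen-order CSV table of per-segment features for one image."""
    rows = []
    for k, seg in enumerate(result.segments, start=1):
        rec = {"image": image_name, "segment_id": k}
        rec.update(extract_features(seg))
        rows.append(rec)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _count_labels(mask: np.ndarray) -> int:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        _, n = ndi.label(mask, structure=np.ones((3, 3), int))
        return n
    return int(np.unique(mask[mask > 0]).size)


def quality_q(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    q2_denominator: str = "gt",
) -> QualityReport:
    """Score a predicted label mask against ground truth.

    ``q2_denominator="gt"`` normalizes misclassified pixels by ground-truth
    mass (default); ``"union"`` uses the symmetric union of both foregrounds.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {gt_mask.shape}")
    gt_fg = gt_mask > 0 if gt_mask.dtype != bool else gt_mask
    pred_fg = pred_mask > 0 if pred_mask.dtype != bool else pred_mask
    n_gt = _count_labels(gt_mask)
    gt_mass = int(gt_fg.sum())
    if n_gt == 0 or gt_mass == 0:
        raise ValueError("ground truth is empty: quality undefined")
    n_pred = _count_labels(pred_mask)
    q1 = 100.0 * abs(n_pred - n_gt) / n_gt
    mis = int((pred_fg & ~gt_fg).sum()) + int((~pred_fg & gt_fg).sum())
    denom = gt_mass if q2_denominator == "gt" else int((pred_fg | gt_fg).sum())
    q2 = min(1.0, mis / denom)
    Q = (1.0 - min(1.0, q1 / 100.0)) * (1.0 - q2)
    return QualityReport(Q=Q, q1=q1, q2=q2, n_detected=n_pred, n_truth=n_gt)


def quality_mean(reports: list[QualityReport]) -> tuple[float, float]:
    """Arithmetic means (Q_m, q1_m) over per-image reports."""
    if not reports:
        raise ValueError("need at least one report")
    return (
        float(np.mean([r.Q for r in reports])),
        float(np.mean([r.q1 for r in reports])),
    )


def circles_to_mask(
    circles: list[tuple[tuple[float, float], float]],
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize (center, radius) circles into a label mask.

    Emulates colony masks from detectors that only report circles.
    Overlapping discs are separated by watershed on the distance transform,
    seeded at the circle centers, so the label count matches the input list.
    """
    out_fg = np.zeros(shape, dtype=bool)
    markers = np.zeros(shape, dtype=np.int32)
    kept = 0
    for (r, c), rad in circles:
        if rad <= 0:
            raise ValueError(f"radius must be positive, got {rad}")
        rr, cc = disk((r, c), rad, shape=shape)
        if rr.size == 0:
            warnings.warn(f"circle at ({r}, {c}) lies fully outside the image; skipped", stacklevel=2)
            continue
        kept += 1
        out_fg[rr, cc] = True
        markers[int(round(min(max(r, 0), shape[0] - 1))), int(round(min(max(c, 0), shape[1] - 1)))] = kept
    if kept == 0:
        return markers
    dist = ndi.distance_transform_edt(out_fg)
    return watershed(-dist, markers, mask=out_fg, connectivity=2).astype(np.int32)
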
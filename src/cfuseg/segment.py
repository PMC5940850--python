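"""Supervised multi-threshold segmentation with BLOB plausibility filtering.

The normalized image is binarized at a sweep of intensity thresholds
``t_i = min(delta*i + t_min, t_max)`` with ``t_min = 0.01``, ``t_max = 0.99``
and ``delta = 0.1`` by default; the per-threshold masks are combined with a
pixelwise OR, so an object detectable at any level survives.  Connected
components of the combined mask are then checked against the a priori
model: anything smaller than ``a_min`` (or, optionally, outside the
intensity band) is discarded, and oversized components are routed to the
watershed de-clumping stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .apriori import AprioriModel
from .core_model import Segment
from .image_prep import NormalizedImage

__all__ = [
    "ThresholdSchedule",
    "threshold_schedule",
    "segment_at_threshold",
    "multithreshold_segment",
    "plausibility_filter",
    "classify_big_blobs",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ThresholdSchedule:
    """Threshold sweep bounds and step; defaults 0.01 .. 0.99 by 0.1."""

    t_min: float = 0.01
    t_max: float = 0.99
    delta: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max < 1):
            raise ValueError(f"need 0 < t_min < t_max < 1, got {self.t_min}, {self.t_max}")
        if not (0 < self.delta <= self.t_max - self.t_min):
            raise ValueError(f"need 0 < delta <= t_max - t_min, got {self.delta}")

    def thresholds(self) -> list[float]:
        return threshold_schedule(self)


def threshold_schedule(cfg: ThresholdSchedule | None = None) -> list[float]:
    """Enumerate ``t_i = min(delta*i + t_min, t_max)``, deduplicated, ascending.

    The index runs 0 .. ceil((t_max - t_min)/delta) so the clamp guarantees
    the last threshold is exactly ``t_max``.
    """
    cfg = cfg or ThresholdSchedule()
    n = int(np.ceil((cfg.t_max - cfg.t_min) / cfg.delta))
    ts = [min(cfg.delta * i + cfg.t_min, cfg.t_max) for i in range(n + 1)]
    out: list[float] = []
    for t in ts:
        if not out or t > out[-1]:
            out.append(round(t, 12))
    return out


def segment_at_threshold(img: NormalizedImage, t: float) -> np.ndarray:
    """Binarize at ``t`` inside the dish mask, holes filled per component."""
    if not 0 < t < 1:
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    mask = (img.pixels >= t) & img.search_mask()
    return ndi.binary_fill_holes(mask)


def multithreshold_segment(
    img: NormalizedImage, schedule: ThresholdSchedule | list[float] | None = None
) -> np.ndarray:
    """Pixelwise OR of the per-threshold segmentations over the sweep."""
    ts = schedule if isinstance(schedule, list) else threshold_schedule(schedule)
    if not ts:
        raise ValueError("threshold schedule is empty")
    out = np.zeros(img.pixels.shape, dtype=bool)
    for t in ts:
        out |= segment_at_threshold(img, t)
    return out


def multithreshold_accumulate(
    img: NormalizedImage,
    model: AprioriModel,
    schedule: ThresholdSchedule | list[float] | None = None,
    max_area_frac: float = 0.10,
) -> np.ndarray:
    """OR-accumulate per-threshold detections that pass a size sanity check.

    A raw OR of nested threshold masks is dominated by the lowest level
    (thresholding is monotone), so each level contributes only its
    plausible components: area inside the fuzzy size support (at least
    ``0.5 * a_min``, the left foot of the size membership) and at most
    ``max_area_frac`` of the search area.  Low levels catch dim colonies,
    high levels resolve bright cores, and plateau-wide blobs (the agar
    surface itself) never enter the accumulator.  The hard ``a_min`` cut is
    applied afterwards by :func:`plausibility_filter` on the combined mask.
    """
    ts = schedule if isinstance(schedule, list) else threshold_schedule(schedule)
    if not ts:
        raise ValueError("threshold schedule is empty")
    cap = max_area_frac * float(img.search_mask().sum())
    out = np.zeros(img.pixels.shape, dtype=bool)
    opener = np.zeros((3, 3), dtype=bool)
    opener[1, :] = opener[:, 1] = True  # radius-1 disc: cuts 1-px noise bridges
    for t in ts:
        mask = segment_at_threshold(img, t)
        mask = ndi.binary_opening(mask, structure=opener)
        lbl, n = ndi.label(mask, structure=_EIGHT)
        if n == 0:
            continue
        areas = ndi.sum_labels(mask, lbl, index=np.arange(1, n + 1))
        good = np.flatnonzero((areas >= 0.5 * model.a_min) & (areas <= cap)) + 1
        if good.size:
            out |= np.isin(lbl, good)
    return out


def plausibility_filter(
    mask: np.ndarray,
    model: AprioriModel,
    img: NormalizedImage | None = None,
) -> tuple[list[Segment], list[Segment]]:
    """Split the mask's 8-connected components into kept and removed.

    Components with area below ``a_min`` are removed; with the intensity
    band enabled (requires ``img``), components whose mean normalized
    intensity falls outside ``[b_min, b_max]`` are removed as well.  The
    fuzzy size membership is retained as a per-segment score downstream; the
    removal itself is the hard ``a_min`` cut.
    """
    mask = np.asarray(mask, dtype=bool)
    pixels = img.pixels if img is not None else None
    lbl, n = ndi.label(mask, structure=_EIGHT)
    kept: list[Segment] = []
    removed: list[Segment] = []
    for k in range(1, n + 1):
        comp = lbl == k
        seg = Segment.from_mask(comp, pixels)
        ok = seg.area >= model.a_min
        if ok and model.intensity_enabled:
            if pixels is None:
                raise ValueError("intensity filtering needs the normalized image")
            ok = model.b_min <= seg.mean_intensity <= model.b_max
        (kept if ok else removed).append(seg)
    return kept, removed


def classify_big_blobs(
    components: list[Segment],
    model: AprioriModel,
    rule: str = "median_x1.3",
) -> tuple[list[Segment], list[Segment]]:
    """Route oversized components to de-clumping.

    The clump cutoff is ``a_big = 1.3 * median(area)`` (reading "the upper
    30% of median" as a 30% margin on the median); components with
    ``area > a_big`` are clumps.  ``rule="p70"`` instead uses the 70th
    percentile of areas as the cutoff.
    """
    if not components:
        raise ValueError("need at least one component")
    areas = np.array([s.area for s in components], dtype=float)
    if rule == "median_x1.3":
        a_big = 1.3 * float(np.median(areas))
    elif rule == "p70":
        a_big = float(np.percentile(areas, 70))
    else:
        raise ValueError(f"unknown big-blob rule {rule!r}")
    singles = [s for s in components if s.area <= a_big]
    clumps = [s for s in components if s.area > a_big]
    return singles, clumps
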
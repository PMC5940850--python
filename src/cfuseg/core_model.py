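"""Shared domain types: fuzzy trapezoidal membership and segmentation containers.

The fuzzy trapezoidal membership function is the scoring primitive used
throughout the pipeline: it grades object areas against the a priori size
band, and it grades candidate watershed splits by expected count and child
size.  A ``Segment`` is one detected object; a ``SegmentationResult`` holds
the full label image plus per-object records and run provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.measure import regionprops

__all__ = [
    "TrapezoidMF",
    "make_trapezoid",
    "eval_trapezoid",
    "Segment",
    "SegmentationResult",
]


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoidal membership function with edges ``p1 <= p2 <= p3 <= p4``.

    Evaluates to 0 outside ``[p1, p4]``, 1 on the plateau ``[p2, p3]`` and
    linearly on the two ramps.  With non-degenerate ramps the feet ``p1`` and
    ``p4`` themselves score 0; a degenerate ramp (``p1 == p2`` or
    ``p3 == p4``) evaluates as a step with value 1 at the shared edge, so the
    function stays total and never divides by zero.
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        edges = (self.p1, self.p2, self.p3, self.p4)
        if not all(np.isfinite(edges)):
            raise ValueError(f"trapezoid edges must be finite, got {edges}")
        names = ("p1", "p2", "p3", "p4")
        for i in range(3):
            if edges[i] > edges[i + 1]:
                raise ValueError(
                    f"trapezoid edges must be non-decreasing: "
                    f"{names[i]}={edges[i]} > {names[i + 1]}={edges[i + 1]}"
                )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        # plateau
        out[(x >= self.p2) & (x <= self.p3)] = 1.0
        # rising ramp
        if self.p2 > self.p1:
            m = (x > self.p1) & (x < self.p2)
            out[m] = (x[m] - self.p1) / (self.p2 - self.p1)
        # falling ramp
        if self.p4 > self.p3:
            m = (x > self.p3) & (x < self.p4)
            out[m] = (self.p4 - x[m]) / (self.p4 - self.p3)
        return float(out) if out.ndim == 0 else out

    @property
    def edges(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


def make_trapezoid(p1: float, p2: float, p3: float, p4: float) -> TrapezoidMF:
    """Build a validated :class:`TrapezoidMF` from its four edge positions."""
    return TrapezoidMF(float(p1), float(p2), float(p3), float(p4))


def eval_trapezoid(mf: TrapezoidMF, x) -> float:
    """Evaluate ``mf`` at ``x`` (scalar or array); result lies in [0, 1]."""
    return mf(x)


@dataclass
class Segment:
    """One detected object: its pixels and basic shape/intensity features.

    Pixels are stored as parallel ``rows``/``cols`` integer arrays; the
    region is 8-connected.  ``mean_intensity`` is measured on the normalized
    (possibly inverted) image, hence lies in [0, 1].
    """

    rows: np.ndarray
    cols: np.ndarray
    area: int
    mean_intensity: float
    eccentricity: float
    equiv_radius: float
    centroid: tuple[float, float]

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    @classmethod
    def from_mask(cls, mask: np.ndarray, image: np.ndarray | None = None) -> "Segment":
        """Build a segment from a boolean mask (one 8-connected component).

        Eccentricity comes from the second central moments of the region
        (best-fit ellipse); degenerate regions (a single pixel, or any region
        whose moments give no defined ellipse) use eccentricity 0.
        """
        mask = np.asarray(mask, dtype=bool)
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            raise ValueError("cannot build a Segment from an empty mask")
        area = int(rr.size)
        props = regionprops(mask.astype(np.uint8))[0]
        try:
            ecc = float(props.eccentricity)
            if not np.isfinite(ecc):
                ecc = 0.0
        except Exception:
            ecc = 0.0
        if area == 1:
            ecc = 0.0
        mean_int = float(np.asarray(image)[rr, cc].mean()) if image is not None else float("nan")
        return cls(
            rows=rr,
            cols=cc,
            area=area,
            mean_intensity=mean_int,
            eccentricity=ecc,
            equiv_radius=float(np.sqrt(area / np.pi)),
            centroid=(float(rr.mean()), float(cc.mean())),
        )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class SegmentationResult:
    """A label image with its per-object segments and run provenance.

    ``label_mask`` uses 0 for background and contiguous ids ``1..N`` for the
    N segments, id ``k`` matching ``segments[k-1]``.  ``meta`` records the
    thresholds used and the optimal H-maxima depth found for each split
    clump.
    """

    label_mask: np.ndarray
    segments: list[Segment]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @classmethod
    def from_label_mask(
        cls,
        label_mask: np.ndarray,
        image: np.ndarray | None = None,
        meta: dict[str, Any] | None = None,
    ) -> "SegmentationResult":
        """Build a result from any integer label image (ids are compacted)."""
        label_mask = np.asarray(label_mask)
        ids = np.unique(label_mask)
        ids = ids[ids > 0]
        out = np.zeros_like(label_mask, dtype=np.int32)
        segments = []
        for new_id, old_id in enumerate(ids, start=1):
            m = label_mask == old_id
            out[m] = new_id
            segments.append(Segment.from_mask(m, image))
        return cls(label_mask=out, segments=segments, meta=dict(meta or {}))

    def check_invariants(self) -> None:
        """Raise if ids are not contiguous or segments disagree with the mask."""
        ids = np.unique(self.label_mask)
        ids = ids[ids > 0]
        expect = np.arange(1, len(self.segments) + 1)
        if not np.array_equal(ids, expect[np.isin(expect, ids)]) or ids.size != len(self.segments):
            raise AssertionError("label ids are not contiguous 1..N")
        for k, seg in enumerate(self.segments, start=1):
            m = self.label_mask == k
            if int(m.sum()) != seg.area or not np.all(m[seg.rows, seg.cols]):
                raise AssertionError(f"segment {k} pixels disagree with label mask")
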
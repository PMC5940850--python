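"""Feedback-tuned H-maxima watershed splitting of clumped colonies.

A component flagged as a clump is split by marker-controlled watershed,
where the markers are the extended maxima of the intensity patch at depth
``h``.  Because no single ``h`` works across clumps, ``h`` is swept over a
grid (0.10 .. 0.30, step 0.01 by default) and each candidate split is
scored with

    Q1(h) = mu1 * mu2

where ``mu1`` grades the child count against the expected count
``n_x = clump_area / a_min`` through a trapezoid with edges
``(1, n_x, 2*n_x, 3*n_x - 1)``, and ``mu2`` grades the child sizes through a
trapezoid with edges ``(0.5*a_min, a_min, 2*a_min, max(2*a_min, a_max))``.
The split with the highest Q1 wins; ties go to the smallest ``h`` (the least
aggressive split), and a clump whose best score is 0 is kept whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from .apriori import AprioriModel
from .core_model import Segment, SegmentationResult, TrapezoidMF
from .image_prep import NormalizedImage

__all__ = [
    "DeclumpConfig",
    "SplitCandidate",
    "seeds_at_h",
    "watershed_split",
    "nx_of",
    "q1_score",
    "optimize_h",
    "declump_all",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class DeclumpConfig:
    """H-maxima depth sweep: bounds and step."""

    h_min: float = 0.10
    h_max: float = 0.30
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.h_min <= self.h_max < 1):
            raise ValueError(f"need 0 < h_min <= h_max < 1, got {self.h_min}, {self.h_max}")
        if not (0 < self.step <= max(self.h_max - self.h_min, self.step)):
            raise ValueError(f"invalid step {self.step}")

    def grid(self) -> list[float]:
        n = int(round((self.h_max - self.h_min) / self.step))
        return [round(self.h_min + i * self.step, 10) for i in range(n + 1)]


@dataclass
class SplitCandidate:
    """One evaluated depth: the children it produces and their Q1 score."""

    h: float
    children: list[np.ndarray]
    n_x: float
    q1: float


def seeds_at_h(img_patch: np.ndarray, mask: np.ndarray, h: float) -> np.ndarray:
    """Extended-maxima transform of the patch at depth ``h``, hole-filled.

    Maxima outside the clump mask are discarded; each connected seed becomes
    one watershed marker.  An empty result means the clump cannot be split
    at this depth.

    The transform is computed classically — regional maxima of the
    greyscale reconstruction of ``patch - h`` under ``patch`` — so that
    equal-height peaks whose saddle is shallower than ``h`` merge into one
    seed through the connecting ridge.
    """
    if not 0 < h < 1:
        raise ValueError(f"depth h must be in (0, 1), got {h}")
    patch = np.asarray(img_patch, dtype=float)
    work = np.where(mask, patch, 0.0)
    hmax = reconstruction(work - h, work, method="dilation")
    seeds = local_maxima(hmax, connectivity=2) & mask
    return ndi.binary_fill_holes(seeds)


def watershed_split(img_patch: np.ndarray, mask: np.ndarray, h: float) -> list[np.ndarray]:
    """Partition the clump mask by marker-controlled watershed at depth ``h``.

    Markers are the seeds from :func:`seeds_at_h`; the flooding surface is
    the complemented patch with minima imposed at the markers (basins grow
    from the seeds only).  Every masked pixel is assigned to exactly one
    basin, so the children partition the clump.  With fewer than two seeds
    the clump is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    seeds = seeds_at_h(img_patch, mask, h)
    markers, n = ndi.label(seeds, structure=_EIGHT)
    if n <= 1:
        return [mask.copy()]
    labels = watershed(-np.asarray(img_patch, dtype=float), markers, mask=mask, connectivity=2)
    children = [labels == k for k in range(1, n + 1)]
    return [c for c in children if c.any()]


def nx_of(mask: np.ndarray, model: AprioriModel) -> float:
    """Expected object count of a clump: foreground pixels over ``a_min``."""
    total = float(np.asarray(mask, dtype=bool).sum())
    if total == 0:
        raise ValueError("empty clump mask")
    return total / model.a_min


def _count_mf(n_x: float) -> TrapezoidMF:
    # n_x < 1 would break edge monotonicity (3n_x - 1 < 2n_x); a clump always
    # holds at least one expected object, so clamp.
    n_x = max(1.0, n_x)
    return TrapezoidMF(1.0, n_x, 2.0 * n_x, 3.0 * n_x - 1.0)


def _size_mf(model: AprioriModel) -> TrapezoidMF:
    a = model.a_min
    return TrapezoidMF(0.5 * a, a, 2.0 * a, max(2.0 * a, model.a_max))


def q1_score(children: list[np.ndarray], model: AprioriModel) -> float:
    """Score a candidate split: count membership times mean size membership."""
    if not children:
        raise ValueError("need at least one child")
    areas = np.array([float(np.asarray(c, bool).sum()) for c in children])
    n_x = areas.sum() / model.a_min
    mu1 = _count_mf(n_x)(float(len(children)))
    mu2 = float(np.mean(_size_mf(model)(areas)))
    return float(mu1 * mu2)


def optimize_h(
    img_patch: np.ndarray,
    mask: np.ndarray,
    model: AprioriModel,
    cfg: DeclumpConfig | None = None,
) -> tuple[float | None, list[np.ndarray], list[SplitCandidate]]:
    """Sweep the depth grid and return the argmax split.

    Returns ``(h_opt, children, candidates)``.  Ties break toward the
    smallest ``h``; if every candidate scores 0 the clump is kept unsplit
    and ``h_opt`` is None.
    """
    cfg = cfg or DeclumpConfig()
    mask = np.asarray(mask, dtype=bool)
    candidates: list[SplitCandidate] = []
    best: SplitCandidate | None = None
    for h in cfg.grid():
        children = watershed_split(img_patch, mask, h)
        cand = SplitCandidate(h=h, children=children, n_x=nx_of(mask, model), q1=q1_score(children, model))
        candidates.append(cand)
        if best is None or cand.q1 > best.q1:
            best = cand
    if best is None or best.q1 == 0.0:
        return None, [mask.copy()], candidates
    return best.h, best.children, candidates


def _merge_small_children(children: list[np.ndarray], a_min: float) -> list[np.ndarray]:
    """Fold children below ``a_min`` into their largest adjacent sibling.

    Keeps pixel conservation within the clump; if a runt touches no sibling
    (cannot happen for watershed partitions of a connected clump, but guard
    anyway) it merges into the largest sibling overall.
    """
    kids = [np.asarray(c, bool) for c in children]
    while len(kids) > 1:
        areas = [int(c.sum()) for c in kids]
        small = [i for i, a in enumerate(areas) if a < a_min]
        if not small:
            break
        i = min(small, key=lambda j: areas[j])
        grown = ndi.binary_dilation(kids[i], structure=_EIGHT)
        adjacent = [j for j in range(len(kids)) if j != i and (grown & kids[j]).any()]
        pool = adjacent or [j for j in range(len(kids)) if j != i]
        j = max(pool, key=lambda k: areas[k])
        kids[j] = kids[j] | kids[i]
        del kids[i]
    return kids


def declump_all(
    result: SegmentationResult,
    img: NormalizedImage,
    model: AprioriModel,
    cfg: DeclumpConfig | None = None,
    clump_ids: list[int] | None = None,
) -> SegmentationResult:
    """Replace every clump in a segmentation by its best watershed split.

    ``clump_ids`` are 1-based segment ids flagged by the big-blob
    classification; children smaller than ``a_min`` are merged back into
    their largest adjacent sibling.  The label mask is rebuilt with
    contiguous ids and per-clump ``h_opt`` recorded in ``meta['h_opt']``.
    """
    cfg = cfg or DeclumpConfig()
    if clump_ids is None:
        from .segment import classify_big_blobs

        _, clumps = classify_big_blobs(result.segments, model)
        clump_ids = [k for k, s in enumerate(result.segments, 1) if any(s is c for c in clumps)]
    clump_set = set(clump_ids)
    shape = result.label_mask.shape
    new_mask = np.zeros(shape, dtype=np.int32)
    h_opts: dict[int, float | None] = {}
    next_id = 0
    segments: list[Segment] = []
    for k, seg in enumerate(result.segments, start=1):
        if k not in clump_set:
            next_id += 1
            new_mask[seg.rows, seg.cols] = next_id
            segments.append(seg)
            continue
        r0, r1 = seg.rows.min(), seg.rows.max() + 1
        c0, c1 = seg.cols.min(), seg.cols.max() + 1
        patch = img.pixels[r0:r1, c0:c1]
        m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        m[seg.rows - r0, seg.cols - c0] = True
        h_opt, children, _ = optimize_h(patch, m, model, cfg)
        children = _merge_small_children(children, model.a_min)
        h_opts[k] = h_opt
        for child in children:
            next_id += 1
            rr, cc = np.nonzero(child)
            new_mask[rr + r0, cc + c0] = next_id
            segments.append(Segment.from_mask(_embed(child, shape, r0, c0), img.pixels))
    meta = dict(result.meta)
    meta["h_opt"] = h_opts
    return SegmentationResult(label_mask=new_mask, segments=segments, meta=meta)


def _embed(patch_mask: np.ndarray, shape: tuple[int, int], r0: int, c0: int) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    h, w = patch_mask.shape
    out[r0 : r0 + h, c0 : c0 + w] = patch_mask
    return out
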
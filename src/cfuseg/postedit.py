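"""Headless post-editing of segmentation results.

The GUI correction step (click to add a missed colony, click to delete a
false detection) maps to two pure operations on a ``SegmentationResult``:
``add_segment`` grows a new object from a seed with the same fast-marching
extraction used for the a priori examples, and ``remove_segment`` deletes by
id or by any interior point.  Edits are journaled as plain text lines so a
batch run's corrections can be replayed and audited.
"""

from __future__ import annotations

import numpy as np

from .apriori import blob_from_seed
from .core_model import Segment, SegmentationResult
from .image_prep import NormalizedImage

__all__ = ["add_segment", "remove_segment", "apply_journal", "parse_journal_line"]


def add_segment(
    result: SegmentationResult,
    img: NormalizedImage,
    seed: tuple[int, int],
) -> SegmentationResult:
    """Grow a new segment at ``seed`` and append it with the next free id.

    The grown blob is clipped against existing segments (their pixels win).
    Seeding inside an existing segment is an error — that object is already
    detected.
    """
    r, c = int(round(seed[0])), int(round(seed[1]))
    existing = result.label_mask[r, c] if _inside(result.label_mask.shape, r, c) else 0
    if existing > 0:
        raise ValueError(f"seed {seed} lies inside existing segment {int(existing)}")
    blob = blob_from_seed(img, (r, c))
    new_mask = blob.to_mask(result.label_mask.shape) & (result.label_mask == 0)
    if not new_mask.any():
        raise ValueError(f"no object at seed {seed}: blob fully overlaps existing segments")
    label_mask = result.label_mask.copy()
    new_id = len(result.segments) + 1
    label_mask[new_mask] = new_id
    segments = list(result.segments) + [Segment.from_mask(new_mask, img.pixels)]
    meta = dict(result.meta)
    meta.setdefault("edits", []).append(f"add {r} {c}")
    return SegmentationResult(label_mask=label_mask, segments=segments, meta=meta)


def remove_segment(
    result: SegmentationResult,
    segment_id: int | None = None,
    point: tuple[int, int] | None = None,
) -> SegmentationResult:
    """Delete one segment, selected by id or by a contained point.

    Remaining ids are compacted to 1..N preserving order; untouched
    segments' pixels are unchanged.
    """
    if (segment_id is None) == (point is None):
        raise ValueError("select exactly one of segment_id or point")
    if point is not None:
        r, c = int(round(point[0])), int(round(point[1]))
        if not _inside(result.label_mask.shape, r, c) or result.label_mask[r, c] == 0:
            raise ValueError(f"no segment at point ({r}, {c})")
        segment_id = int(result.label_mask[r, c])
    if not 1 <= segment_id <= len(result.segments):
        raise ValueError(f"no segment with id {segment_id} (have 1..{len(result.segments)})")
    label_mask = np.zeros_like(result.label_mask)
    segments: list[Segment] = []
    for k, seg in enumerate(result.segments, start=1):
        if k == segment_id:
            continue
        segments.append(seg)
        label_mask[seg.rows, seg.cols] = len(segments)
    meta = dict(result.meta)
    meta.setdefault("edits", []).append(f"remove id {segment_id}")
    return SegmentationResult(label_mask=label_mask, segments=segments, meta=meta)


def parse_journal_line(line: str):
    """Parse one edit line: ``add r c`` / ``remove id k`` / ``remove at r c``."""
    tok = line.split()
    if not tok or tok[0].startswith("#"):
        return None
    if tok[0] == "add" and len(tok) == 3:
        return ("add", (int(tok[1]), int(tok[2])))
    if tok[0] == "remove" and len(tok) == 3 and tok[1] == "id":
        return ("remove_id", int(tok[2]))
    if tok[0] == "remove" and len(tok) == 4 and tok[1] == "at":
        return ("remove_at", (int(tok[2]), int(tok[3])))
    raise ValueError(f"bad journal line: {line!r}")


def apply_journal(
    result: SegmentationResult,
    img: NormalizedImage,
    lines,
) -> SegmentationResult:
    """Replay a text edit journal against a result."""
    for line in lines:
        op = parse_journal_line(line)
        if op is None:
            continue
        kind, arg = op
        if kind == "add":
            result = add_segment(result, img, arg)
        elif kind == "remove_id":
            result = remove_segment(result, segment_id=arg)
        else:
            result = remove_segment(result, point=arg)
    return result


def _inside(shape: tuple[int, int], r: int, c: int) -> bool:
    return 0 <= r < shape[0] and 0 <= c < shape[1]
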
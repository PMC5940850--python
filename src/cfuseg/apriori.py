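"""A priori model extraction: seed-grown example blobs and the fuzzy size band.

The method is supervised by two (or more) example objects: the user marks a
small and a large colony, each seed is grown into its full object by a
front-propagation (fast-marching) region extraction, and the observed areas
``a_min``/``a_max`` parameterize a trapezoidal size membership with edges
``(0.5*a_min, a_min, a_max, 2*a_max)``.  Optionally the example mean
intensities define a plausible intensity band ``[b_min, b_max]`` with
``b_min = 0.5*min(b)`` and ``b_max = min(1, 1.5*max(b))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.graph import MCP_Geometric

from .core_model import Segment, TrapezoidMF
from .image_prep import NormalizedImage

__all__ = ["AprioriModel", "blob_from_seed", "build_apriori", "apriori_from_areas"]


@dataclass
class AprioriModel:
    """Size bounds, fuzzy size membership, and optional intensity band."""

    a_min: float
    a_max: float
    size_mf: TrapezoidMF
    intensity_enabled: bool = False
    b_min: float = 0.0
    b_max: float = 1.0
    example_blobs: list[Segment] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "a_min": self.a_min,
                "a_max": self.a_max,
                "size_mf_edges": list(self.size_mf.edges),
                "intensity_enabled": self.intensity_enabled,
                "b_min": self.b_min,
                "b_max": self.b_max,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AprioriModel":
        d = json.loads(text)
        return cls(
            a_min=d["a_min"],
            a_max=d["a_max"],
            size_mf=TrapezoidMF(*d["size_mf_edges"]),
            intensity_enabled=d["intensity_enabled"],
            b_min=d["b_min"],
            b_max=d["b_max"],
        )


class SeedError(ValueError):
    """Raised when a seed point does not sit on a growable object."""


def _travel_time(img: NormalizedImage, seed: tuple[int, int], sigma: float) -> np.ndarray:
    """Geodesic arrival time from the seed on an intensity-similarity speed map.

    Speed F(p) = 1 / (1 + ((I(p) - Ibar_seed) / sigma)^2) with Ibar_seed the
    mean of the 3x3 seed neighbourhood; the front-propagation cost is 1/F,
    solved with an 8-connected geometric minimum-cost path (the discrete
    counterpart of the eikonal solve).
    """
    px = img.pixels
    r, c = seed
    r0, r1 = max(0, r - 1), min(px.shape[0], r + 2)
    c0, c1 = max(0, c - 1), min(px.shape[1], c + 2)
    seed_mean = float(px[r0:r1, c0:c1].mean())
    speed = 1.0 / (1.0 + ((px - seed_mean) / sigma) ** 2)
    cost = 1.0 / speed
    cost[~img.search_mask()] = np.inf
    mcp = MCP_Geometric(cost, fully_connected=True)
    t, _ = mcp.find_costs([(r, c)])
    return t


def blob_from_seed(
    img: NormalizedImage,
    seed: tuple[int, int],
    sigma: float = 0.1,
    n_levels: int = 32,
    min_area: int = 9,
    max_dish_frac: float = 0.25,
) -> Segment:
    """Grow one object from a seed pixel by fast-marching region extraction.

    The region is the arrival-time sublevel set cut at the level T* that
    maximizes the mean image-gradient magnitude along the region boundary,
    swept over ``n_levels`` candidate times.  Degenerate results (fewer than
    ``min_area`` pixels, or flooding more than ``max_dish_frac`` of the
    search area) raise :class:`SeedError`.
    """
    r, c = int(round(seed[0])), int(round(seed[1]))
    search = img.search_mask()
    if not (0 <= r < img.pixels.shape[0] and 0 <= c < img.pixels.shape[1]) or not search[r, c]:
        raise SeedError(f"seed {seed} lies outside the search area")
    t = _travel_time(img, (r, c), sigma)
    finite = np.isfinite(t)
    cap = max_dish_frac * float(search.sum())
    ts = np.sort(t[finite])
    ts = ts[ts > 0]
    if ts.size < min_area:
        raise SeedError(f"no object at seed {seed}: region degenerates")
    # candidate cut levels at geometrically spaced region areas: arrival
    # times inside an object are tiny compared to the background, so
    # sampling times directly would skip the object boundary entirely
    n_hi = min(int(cap), ts.size)
    gy, gx = np.gradient(img.pixels)
    gmag = np.hypot(gy, gx)

    def score_at(area_target: int):
        region = finite & (t <= ts[area_target - 1])
        # keep only the component containing the seed
        lbl, _ = ndi.label(region, structure=np.ones((3, 3), dtype=int))
        region = ndi.binary_fill_holes(lbl == lbl[r, c])
        area = int(region.sum())
        if area < min_area or area > cap:
            return -np.inf, None
        boundary = region & ~ndi.binary_erosion(region)
        return (float(gmag[boundary].mean()) if boundary.any() else -np.inf), region

    coarse = np.unique(np.geomspace(min_area, n_hi, n_levels).astype(int))
    scores = [score_at(a) for a in coarse]
    best_i = int(np.argmax([s for s, _ in scores]))
    best_score, best_mask = scores[best_i]
    # refine: linear sweep between the coarse neighbours of the winner
    lo = coarse[max(0, best_i - 1)]
    hi = coarse[min(len(coarse) - 1, best_i + 1)]
    for a in np.unique(np.linspace(lo, hi, n_levels).astype(int)):
        score, region = score_at(int(a))
        if score > best_score:
            best_score, best_mask = score, region
    if best_mask is None:
        raise SeedError(f"no object at seed {seed}: region degenerates or floods")
    # a real object boundary must stand out against the ambient gradient;
    # seeds on flat background otherwise flood to an arbitrary noise contour
    ambient = float(np.median(gmag[search]))
    if not np.isfinite(best_score) or best_score < 3.0 * ambient:
        raise SeedError(f"no object at seed {seed}: boundary indistinct from background")
    # snap to an amplitude level set: the gradient cut localizes the
    # boundary only to ~1 px, which costs up to 10% area on small objects
    px = img.pixels
    inner = ndi.binary_erosion(best_mask, iterations=2)
    inner_mean = float(px[inner if inner.any() else best_mask].mean())
    halo = ndi.binary_dilation(best_mask, iterations=5) & ~best_mask & search
    outer_mean = float(px[halo].mean()) if halo.any() else 0.0
    # objects are bright on dark: a region no brighter than its surroundings
    # is a background flood that stopped against some other object's edge
    if inner_mean <= outer_mean + 0.02:
        raise SeedError(f"no object at seed {seed}: region not brighter than surroundings")
    # quarter-amplitude level: exact on step edges, and close to the full
    # support of dome-profiled colonies (a half-amplitude cut would trim a
    # smooth dome to ~2/3 of its footprint)
    level = outer_mean + 0.25 * (inner_mean - outer_mean)
    cand = (px >= level) & ndi.binary_dilation(best_mask, iterations=3) & search
    cand = ndi.binary_fill_holes(cand)
    lbl, _ = ndi.label(cand, structure=np.ones((3, 3), dtype=int))
    if lbl[r, c] > 0:
        snapped = lbl == lbl[r, c]
        if min_area <= int(snapped.sum()) <= cap:
            best_mask = snapped
    return Segment.from_mask(best_mask, img.pixels)


def build_apriori(blobs: list[Segment], use_intensity: bool = False) -> AprioriModel:
    """Build the fuzzy a priori model from example blobs.

    ``a_min``/``a_max`` are the min/max example areas; the size membership
    has edges ``(0.5*a_min, a_min, a_max, 2*a_max)``.  With intensity
    enabled, ``b_min = 0.5*min(b)`` and ``b_max = min(1, 1.5*max(b))`` over
    the example mean intensities.
    """
    if not blobs:
        raise ValueError("need at least one example blob")
    areas = [float(b.area) for b in blobs]
    if min(areas) <= 0:
        raise ValueError("example blob areas must be positive")
    a_min, a_max = min(areas), max(areas)
    model = AprioriModel(
        a_min=a_min,
        a_max=a_max,
        size_mf=TrapezoidMF(0.5 * a_min, a_min, a_max, 2.0 * a_max),
        example_blobs=list(blobs),
    )
    if use_intensity:
        ints = [b.mean_intensity for b in blobs]
        model.intensity_enabled = True
        model.b_min = 0.5 * min(ints)
        model.b_max = min(1.0, 1.5 * max(ints))
    return model


def apriori_from_areas(
    a_min: float,
    a_max: float,
    b_min: float | None = None,
    b_max: float | None = None,
) -> AprioriModel:
    """Build a model directly from known size bounds (batch reuse, tests)."""
    if not 0 < a_min <= a_max:
        raise ValueError(f"need 0 < a_min <= a_max, got {a_min}, {a_max}")
    model = AprioriModel(
        a_min=float(a_min),
        a_max=float(a_max),
        size_mf=TrapezoidMF(0.5 * a_min, a_min, a_max, 2.0 * a_max),
    )
    if b_min is not None and b_max is not None:
        model.intensity_enabled = True
        model.b_min, model.b_max = float(b_min), float(b_max)
    return model
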
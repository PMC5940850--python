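"""Synthetic plate and clump generation with pixel-exact ground truth.

Every pipeline stage is exercised on generated imagery: a circular dish
with a bright rim ring (the reflectance artifact real plates show), near-
circular colonies rendered as clipped cosine intensity bumps, optional
touching clumps, additive Gaussian noise and optional contrast inversion.
The cosine profile gives the watershed a realistic smooth topography and
makes the intensity prominence of a clump's saddle a controllable ground
truth for the H-maxima depth.  All randomness flows from the single seed in
the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlateSpec", "generate_plate", "generate_clump"]


@dataclass(frozen=True)
class PlateSpec:
    """Everything needed to render one plate deterministically."""

    shape: tuple[int, int] = (512, 512)
    dish_center: tuple[float, float] | None = None  # None => image center
    dish_radius: float | None = None  # None => 0.42 * min side; 0 => no dish
    n_colonies: int = 25
    radius_range: tuple[float, float] = (10.0, 20.0)
    clump: tuple[int, float] | None = None  # (k discs, overlap fraction)
    background_level: float = 0.05
    dish_level: float = 0.10
    colony_level: float = 0.85
    rim_level: float = 0.55
    rim_width: float = 3.0
    shoulder: float = 2.0
    noise_sd: float = 0.02
    inverted: bool = False
    min_gap: float = 2.0  # minimum clearance between colony supports, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError(f"bad radius range {self.radius_range}")
        if self.n_colonies < 0 or self.noise_sd < 0:
            raise ValueError("n_colonies and noise_sd must be non-negative")
        if self.clump is not None and (self.clump[0] < 1 or not 0 <= self.clump[1] < 1):
            raise ValueError(f"bad clump spec {self.clump}")


def _cos_bump(dist: np.ndarray, radius: float, shoulder: float = 4.0) -> np.ndarray:
    """Unit-peak clipped cosine profile: 1 at the center, 0 at the radius.

    ``shoulder`` sharpens the falloff (profile = cos(pi/2 * (d/r)^shoulder)):
    real colonies are flat-topped with a steep edge, while the interior stays
    smooth enough to give the watershed a usable topography.
    """
    prof = np.cos(0.5 * np.pi * np.clip(dist / radius, 0.0, 1.0) ** shoulder)
    prof[dist > radius] = 0.0
    return prof


def generate_plate(spec: PlateSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a plate; returns (image, truth label mask, dish mask).

    Colonies are placed uniformly inside the dish without mutual overlap
    (except for the requested clump, whose members touch); placement that
    cannot fit after bounded retries raises.  Truth labels are 1..N, one per
    colony; clump boundary pixels go to the nearest colony center.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[:h, :w].astype(float)
    cy, cx = spec.dish_center if spec.dish_center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    dish_r = spec.dish_radius if spec.dish_radius is not None else 0.42 * min(h, w)

    img = np.full((h, w), spec.background_level)
    dish_dist = np.hypot(yy - cy, xx - cx)
    if dish_r > 0:
        dish_mask = dish_dist <= dish_r
        img[dish_mask] = spec.dish_level
        rim = (dish_dist > dish_r) & (dish_dist <= dish_r + spec.rim_width)
        img[rim] = spec.rim_level
    else:
        dish_mask = np.ones((h, w), dtype=bool)

    # decide colony centers/radii; clump members count toward n_colonies
    placements: list[tuple[float, float, float]] = []  # (row, col, radius)

    def fits(r0: float, c0: float, rad: float, gap: float | None = None) -> bool:
        gap = spec.min_gap if gap is None else gap
        if dish_r > 0:
            if np.hypot(r0 - cy, c0 - cx) + rad + spec.rim_width + 2 > dish_r:
                return False
        else:
            if not (rad < r0 < h - 1 - rad and rad < c0 < w - 1 - rad):
                return False
        return all(np.hypot(r0 - pr, c0 - pc) > rad + prad + gap for pr, pc, prad in placements)

    clump_members: list[int] = []
    n_single = spec.n_colonies
    if spec.clump is not None:
        k, overlap = spec.clump
        n_single = max(0, spec.n_colonies - k)
        rad = float(np.mean(spec.radius_range))
        d = 2.0 * rad * (1.0 - overlap)
        placed = False
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi)
            r0 = rng.uniform(0, h - 1)
            c0 = rng.uniform(0, w - 1)
            centers = [(r0 + i * d * np.sin(theta), c0 + i * d * np.cos(theta)) for i in range(k)]
            # the chain must fit as a unit, ignoring intra-chain contact
            saved = list(placements)
            ok = True
            for rr, cc in centers:
                if not fits(rr, cc, rad, gap=-2 * rad):  # allow chain self-contact
                    ok = False
                    break
                placements.append((rr, cc, rad))
            if ok and all(
                np.hypot(rr - pr, cc - pc) > rad + prad + spec.min_gap
                for rr, cc in centers
                for pr, pc, prad in saved
            ):
                clump_members = list(range(len(saved), len(saved) + k))
                placed = True
                break
            placements = saved
        if not placed:
            raise RuntimeError("could not place the requested clump inside the dish")

    tries = 0
    while sum(1 for i in range(len(placements)) if i not in clump_members) < n_single:
        tries += 1
        if tries > 500 * max(1, n_single):
            raise RuntimeError("infeasible packing: colonies do not fit inside the dish")
        rad = rng.uniform(*spec.radius_range)
        r0 = rng.uniform(0, h - 1)
        c0 = rng.uniform(0, w - 1)
        if fits(r0, c0, rad):
            placements.append((r0, c0, rad))

    truth = np.zeros((h, w), dtype=np.int32)
    best_dist = np.full((h, w), np.inf)
    for label, (r0, c0, rad) in enumerate(placements, start=1):
        dist = np.hypot(yy - r0, xx - c0)
        bump = _cos_bump(dist, rad, spec.shoulder)
        base = spec.dish_level if dish_r > 0 else spec.background_level
        img = np.maximum(img, base + (spec.colony_level - base) * bump)
        inside = dist <= rad
        closer = inside & (dist < best_dist)
        truth[closer] = label
        best_dist[closer] = dist[closer]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if spec.inverted:
        img = 1.0 - img
    return img, truth, dish_mask


def generate_clump(
    k: int,
    overlap: float = 0.3,
    radius: float = 25.0,
    prominence: float = 0.2,
    pad: int = 8,
    shoulder: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a chain of ``k`` overlapping colonies as an isolated patch.

    Peaks sit at intensity 1.0 on a 0.0 background and the saddle between
    adjacent members is rescaled to exactly ``1 - prominence``, so the
    extended-maxima transform separates the members for depths below
    ``prominence`` and merges them above it.  Returns (patch, truth labels).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if not 0 < prominence < 1:
        raise ValueError(f"prominence must be in (0, 1), got {prominence}")
    d = 2.0 * radius * (1.0 - overlap)
    length = int(np.ceil((k - 1) * d + 2 * radius)) + 2 * pad
    height = int(np.ceil(2 * radius)) + 2 * pad
    yy, xx = np.mgrid[:height, :length].astype(float)
    cy = (height - 1) / 2.0
    centers = [(cy, pad + radius + i * d) for i in range(k)]
    patch = np.zeros((height, length))
    truth = np.zeros((height, length), dtype=np.int32)
    best = np.full((height, length), np.inf)
    for label, (r0, c0) in enumerate(centers, start=1):
        dist = np.hypot(yy - r0, xx - c0)
        patch = np.maximum(patch, _cos_bump(dist, radius, shoulder))
        inside = dist <= radius
        closer = inside & (dist < best)
        truth[closer] = label
        best[closer] = dist[closer]
    if k > 1 and d / 2.0 < radius:
        # analytic saddle of the cosine profile at half the center spacing
        s = float(np.cos(0.5 * np.pi * ((d / 2.0) / radius) ** shoulder))
        scale = prominence / (1.0 - s)
        fg = patch > 0
        patch[fg] = np.clip(1.0 - (1.0 - patch[fg]) * scale, 0.0, 1.0)
    return patch, truth
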
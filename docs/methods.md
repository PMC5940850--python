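# Methods

This note documents the models and numerical choices behind `cfuseg`, what
the synthetic data emulates, and where the design was genuinely open.

## Pipeline model and assumptions

The method is supervised object detection for bright, roughly convex
objects (bacterial colonies, cell colonies) on a darker, locally flat
background inside a circular container.  Its assumptions, in order of
importance:

- objects are brighter than their immediate surroundings (dark-on-bright
  plates are auto-inverted first, decided by whether the median intensity
  inside the dish exceeds 0.5 after normalization);
- object sizes fall in a band the user can exemplify with one small and
  one large example — everything size-related is expressed in units of the
  example areas, so the pipeline is resolution-independent;
- touching objects form intensity saddles shallower than their peaks, so
  marker depth (H-maxima) separates them.

Preprocessing: channel reduction (Rec.709 luminance by default; a
max-contrast and named-channel policy exist for fluorescence), Gaussian
denoising (`smooth_sigma`, default 1 px — the first pipeline stage; set 0
to disable), min-max normalization to [0, 1], dish extraction, optional
inversion.

## Threshold sweep and why plausibility is applied per level

Binarization at a single threshold either merges dim halos or loses faint
colonies.  The sweep `t_i = min(δ·i + t_min, t_max)` (defaults 0.01, 0.99,
0.1; the index runs to `ceil((t_max − t_min)/δ)` so the clamp guarantees
`t_max` is visited) views the image at eleven levels.  A plain OR of the
per-level masks is mathematically the `t_min` mask alone — thresholding is
monotone — so the OR accumulator (`multithreshold_accumulate`) admits only
*plausible* components from each level: area at least `0.5·a_min` (the
left foot of the size membership) and at most 10% of the search area
(`max_area_frac`).  Plate-scale plateau components never enter; dim
colonies are caught at low levels and bright cores at high ones.  The
strict `a_min` cut and the optional intensity band are applied once, on
the accumulated mask, by `plausibility_filter`.  The literal pure-OR
operation is kept as `multithreshold_segment` for composition and testing.

A radius-1 binary opening is applied per level inside the accumulator to
cut one-pixel percolation bridges between an object and near-threshold
background speckle; it is shape-preserving at colony scales.

## Dish extraction

The container detection method was an open design point.  `cfuseg` uses a
circular Hough transform over a Canny edge map (σ = 2), sweeping radii
between 25% and 60% of the shorter image side on a ≤256 px working copy,
then refining the winning radius at 1 px resolution at full scale — the
downscaling and edge blur otherwise bias the radius by several pixels.
The disc is eroded by 1.5% of its radius plus 2 px: the accumulator may
lock onto either edge of the bright rim ring, and a partially included
rim would close into a ring that hole-filling expands to the entire dish
at low thresholds.  If no circle clears the accumulator floor (0.35) the
whole image is searched and a warning is emitted.  Square containers and
multi-well gridding are out of scope.

## Fast-marching blob extraction

`blob_from_seed` grows one object from a seed pixel.  Speed map
`F(p) = 1/(1 + ((I(p) − Ī_seed)/σ)²)` with `Ī_seed` the 3×3 seed
neighbourhood mean and σ = 0.1; arrival times are geodesic travel times
(8-connected `MCP_Geometric` on cost 1/F, the discrete front-propagation
solve).  The region is the arrival-time sublevel set whose boundary
maximizes mean gradient magnitude, searched over 32 geometrically spaced
region areas (times themselves are useless as a sampling axis: interior
times are tiny, background times huge) followed by a linear refinement
between the winner's neighbours.  Because a gradient argmax localizes the
boundary only to ~1 px — up to 10% area error on a 10 px-radius object —
the cut is then snapped to the quarter-amplitude level set between the
region interior mean and the surrounding halo mean: exact on step edges,
≈84% of the footprint of a smooth dome.

Degenerate seeds raise: regions under 9 px or flooding more than 25% of
the search area, boundaries that do not exceed 3× the ambient median
gradient (flat background), and regions not brighter than their halo
(background floods that stopped against another object's edge).  Interior
holes are filled before scoring so an enveloped bright object cannot lend
its edge to a background flood.

## Feedback watershed

For each clump the depth grid is `h_min + i·step` (defaults 0.10–0.30,
step 0.01, 21 points).  Seeds at depth `h` are the classical extended
maxima: regional maxima of the greyscale reconstruction of `patch − h`
under `patch`.  This matters: the residue-based variant in common use
(`f − rec ≥ h`) keeps exactly-equal peaks separate at every depth, so twin
colonies would never merge as `h` grows and the feedback sweep would lose
its signal on noiseless fixtures.  Splitting is marker-controlled
watershed on the complemented patch restricted to the clump mask; every
masked pixel is assigned to a basin, so children partition the clump
exactly (no separate watershed-line ownership step is needed).

Scoring: `Q₁ = µ₁·µ₂` with µ₁ the count trapezoid `(1, n_x, 2n_x, 3n_x−1)`
evaluated at the child count and µ₂ the mean child-size membership with
edges `(0.5a_min, a_min, 2a_min, max(2a_min, a_max))`.  `n_x` is clamped to
≥1 (below that the count edges would disorder; a flagged clump always holds
at least one expected object).  µ₂ aggregates children by arithmetic mean:
symmetric, bounded, reduces to the single-child value.  Ties break toward
smaller `h` (the least aggressive split); a clump whose best score is 0 is
kept whole and flagged (`h_opt = None`).  Children below `a_min` are merged
into their largest adjacent sibling rather than deleted, preserving pixel
conservation.  Trapezoid conventions: value 1 on the closed plateau, 0 at
and beyond the feet; a degenerate ramp (`p1 = p2` or `p3 = p4`) is a step
with value 1 at the shared edge, keeping evaluation total.

## Quality measure

`q₁ = 100·|n_pred − n_gt|/n_gt` (percent, counts only) and
`q₂ = (FP + FN)/|gt foreground|` clamped to 1 (pixels only; a symmetric
union denominator is available via `q2_denominator="union"`).  The exact
combination rule was open; `cfuseg` uses

`Q = (1 − min(1, q₁/100)) · (1 − q₂)`

which satisfies the required properties — Q ∈ [0, 1], Q = 1 exactly for a
perfect segmentation, Q = 0 for an empty one, monotone degradation as
pixels are corrupted — and is a documented, swappable strategy rather than
a claim about any particular legacy implementation.

## Control/test analytics

Colony-size densities use a Gaussian KDE with an explicit bandwidth in
pixels² (`bw = 2000` default at plate scale, 512 evaluation points).  The
grid extends 4·bw beyond the data range: wide enough that the trapezoid
integral of the density is 1 to three decimals (a ±3σ truncation holds
only 0.99730 mass), while still showing the negative-size extrapolation
tail that a smooth kernel inevitably produces — it does not indicate
negative colony areas.  Size change per control/test pair is the ratio of
total areas (test/control), control normalized to 1, with mean-area as a
config alternative; the mean over pairs is reported alongside absolute
counts per group.

## Synthetic data: what it does and does not emulate

`generate_plate` renders a circular dish (interior level 0.10 on a 0.05
background), a bright rim ring (0.55, 3 px — the reflectance artifact that
plagues real plates), colonies as clipped-cosine domes
`cos(π/2·(d/r)^s)` with shoulder exponent s = 2 (flat-ish top, steep but
smooth edge), peak 0.85, radii 10–20 px, additive Gaussian noise
(sd 0.02), optional inversion, and optional k-colony chains at a given
overlap.  `generate_clump` additionally rescales the chain so the
inter-peak saddle sits exactly at `1 − prominence`, making the merge depth
of the extended maxima a construction parameter (up to ~0.02 rasterization
error at the half-spacing pixel).  Ground truth is pixel-exact; clump
boundary pixels go to the nearest colony center.

Not emulated: agar texture, uneven illumination, satellite colonies,
out-of-focus blur, color variation between species, non-circular
containers.  Passing the synthetic benchmark therefore demonstrates the
pipeline's mechanics (detection, de-clumping, scoring) under controlled
conditions, not robustness to every real acquisition artifact; on real
data the post-editing journal exists precisely because no automatic
pipeline is perfect.

## Problem sizes used in tests

The test suite and behavioral acceptance checks run on 512×512 plates
(12 plates at 12–40 colonies for the end-to-end benchmark), 50–100
generated clumps for the depth-optimization and recovery checks, and
discs of radius 10–60 px (20 seeds) for fast-marching recovery — sizes
chosen so the full suite completes in a couple of minutes on one core
while still exercising every code path at realistic colony scales.

## Known limitations

- The per-level oversize cut (10% of search area) would suppress a single
  object genuinely covering most of the dish (confluent growth); such
  plates are outside the counting regime anyway.
- Smoothing (σ = 1) spreads detected boundaries ~1 px outward; on objects
  of radius ≲10 px this costs several percent of pixel accuracy (counts
  are unaffected).
- Dish detection assumes one dominant circular container; multiple dishes
  per image are not handled.
- The eccentricity filter is off by default and is a plain threshold; no
  calibrated shape prior is claimed.
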
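"""Image loading, channel selection, normalization, inversion and dish masking.

Plate photographs arrive as 8/16-bit TIFF/PNG/JPEG with 1-4 channels and
either bright colonies on a dark dish or the reverse.  Everything downstream
works on a single-channel float image normalized to [0, 1] with bright
objects, restricted to the interior of the (optionally auto-detected)
circular dish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks, rescale

__all__ = [
    "NormalizedImage",
    "load_image",
    "select_channel",
    "normalize_image",
    "maybe_invert",
    "extract_dish_mask",
    "prepare_image",
    "DishConfig",
]

#: standard Rec.709 luminance weights used by skimage's rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class NormalizedImage:
    """Single-channel image scaled to [0, 1] plus preprocessing provenance."""

    pixels: np.ndarray
    inverted: bool = False
    dish_mask: np.ndarray | None = None
    constant_input: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def search_mask(self) -> np.ndarray:
        """The region in which objects are searched (dish interior or all)."""
        if self.dish_mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.dish_mask


def load_image(path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG image as a (H, W) or (H, W, C) numeric array."""
    return np.asarray(iio.imread(path))


def select_channel(raw: np.ndarray, policy: str = "luminance") -> np.ndarray:
    """Reduce a 1-4 channel image to one channel.

    Policies: ``luminance`` (Rec.709 weighted RGB average, alpha ignored),
    ``max-contrast`` (channel with the largest standard deviation), or a
    named channel among ``R``/``G``/``B``/``A`` or a 0-based ``channel:i``.
    """
    raw = np.asarray(raw)
    if raw.ndim == 2:
        return raw.astype(float)
    if raw.ndim != 3 or not 1 <= raw.shape[2] <= 4:
        raise ValueError(f"expected (H, W) or (H, W, 1..4) image, got shape {raw.shape}")
    if raw.shape[2] == 1:
        return raw[:, :, 0].astype(float)
    chans = raw.astype(float)
    if policy == "luminance":
        rgb = chans[:, :, :3]
        if rgb.shape[2] < 3:  # 2-channel image: plain average
            return rgb.mean(axis=2)
        return rgb @ _LUMA
    if policy == "max-contrast":
        stds = [chans[:, :, i].std() for i in range(chans.shape[2])]
        return chans[:, :, int(np.argmax(stds))]
    names = "RGBA"[: chans.shape[2]]
    if policy.upper() in names:
        return chans[:, :, names.index(policy.upper())]
    if policy.startswith("channel:"):
        i = int(policy.split(":", 1)[1])
        if 0 <= i < chans.shape[2]:
            return chans[:, :, i]
    raise ValueError(
        f"unknown channel {policy!r}; available: {', '.join(names)}, "
        f"channel:0..{chans.shape[2] - 1}, luminance, max-contrast"
    )


def normalize_image(raw: np.ndarray) -> NormalizedImage:
    """Rescale intensities to [0, 1] via (I - I_min) / (I_max - I_min).

    A constant image cannot be rescaled; it maps to all zeros and the result
    carries ``constant_input=True`` alongside an emitted warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("image must have at least 2 pixels")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        warnings.warn("constant image: normalization returns all zeros", stacklevel=2)
        return NormalizedImage(pixels=np.zeros_like(raw), constant_input=True)
    return NormalizedImage(pixels=(raw - lo) / (hi - lo))


def maybe_invert(img: NormalizedImage, mode: str = "auto") -> NormalizedImage:
    """Flip contrast so objects are bright on dark.

    ``auto`` inverts when the median pixel inside the dish mask exceeds 0.5:
    colonies occupy a minority of the plate, so a bright median means a
    bright background.  ``always``/``never`` force the choice.
    """
    if mode not in ("auto", "never", "always"):
        raise ValueError(f"invert mode must be auto|never|always, got {mode!r}")
    do = mode == "always"
    if mode == "auto":
        inside = img.pixels[img.search_mask()]
        do = bool(np.median(inside) > 0.5)
    if not do:
        return NormalizedImage(img.pixels, img.inverted, img.dish_mask, img.constant_input)
    return NormalizedImage(1.0 - img.pixels, not img.inverted, img.dish_mask, img.constant_input)


@dataclass
class DishConfig:
    """Parameters of the circular-Hough dish search."""

    radius_frac_range: tuple[float, float] = (0.25, 0.60)  # of min image side
    n_radii: int = 24
    confidence_floor: float = 0.35  # min normalized accumulator peak
    rim_erosion_frac: float = 0.015  # shave this fraction of the radius ...
    rim_margin_px: float = 2.0  # ... plus this absolute margin
    work_size: int = 256  # Hough runs on an image downscaled to this side


def extract_dish_mask(img: NormalizedImage, cfg: DishConfig | None = None) -> NormalizedImage:
    """Locate the circular dish and attach its interior as ``dish_mask``.

    A circular Hough transform over a Canny edge map sweeps radii between 25%
    and 60% of the shorter image side (on a downscaled working copy), then
    refines the winning radius at 1 px resolution; the disc is eroded by
    1.5% of its radius plus a fixed 2 px so the rim ring stays strictly
    outside whichever rim edge the accumulator locks onto (a partially
    included bright ring would otherwise close and hole-fill the whole
    dish at low thresholds).  If no circle clears the confidence floor the
    whole image is searched (all-true mask, warning).
    """
    cfg = cfg or DishConfig()
    px = img.pixels
    h, w = px.shape
    scale = min(1.0, cfg.work_size / min(h, w))
    small = rescale(px, scale, anti_aliasing=True) if scale < 1.0 else px
    edges = canny(small, sigma=2.0)
    rmin = max(4, int(cfg.radius_frac_range[0] * min(small.shape)))
    rmax = max(rmin + 1, int(cfg.radius_frac_range[1] * min(small.shape)))
    radii = np.unique(np.linspace(rmin, rmax, cfg.n_radii).astype(int))
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=1)
    found = len(accums) > 0 and float(accums[0]) >= cfg.confidence_floor
    if not found:
        warnings.warn("no dish found above confidence floor; searching whole image", stacklevel=2)
        mask = np.ones_like(px, dtype=bool)
    else:
        cy, cx, r = cys[0] / scale, cxs[0] / scale, rads[0] / scale
        if scale < 1.0:
            # refine at full resolution: downscaling + edge blur bias the
            # coarse radius by several px, which matters for rim exclusion
            step = (rmax - rmin) / max(1, len(radii) - 1) / scale
            fine_edges = canny(px, sigma=2.0)
            fine = np.arange(max(4, int(r - step)), int(r + step) + 2)
            fa = hough_circle(fine_edges, fine)
            f_accums, f_cxs, f_cys, f_rads = hough_circle_peaks(fa, fine, total_num_peaks=1)
            if len(f_accums):
                cy, cx, r = float(f_cys[0]), float(f_cxs[0]), float(f_rads[0])
        r_in = r * (1.0 - cfg.rim_erosion_frac) - cfg.rim_margin_px
        yy, xx = np.ogrid[:h, :w]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_in**2
    return NormalizedImage(px, img.inverted, mask, img.constant_input)


def prepare_image(
    raw: np.ndarray,
    channel_policy: str = "luminance",
    invert_mode: str = "auto",
    find_dish: bool = True,
    dish_cfg: DishConfig | None = None,
    smooth_sigma: float = 1.0,
) -> NormalizedImage:
    """Full preprocessing chain: channel -> denoise -> normalize -> dish -> invert.

    ``smooth_sigma`` is the Gaussian noise-removal scale in pixels (0
    disables it); the image is re-normalized afterwards so the [0, 1] range
    invariant holds.  Inversion runs last so the auto decision uses the
    median inside the dish.
    """
    plane = select_channel(raw, channel_policy)
    if smooth_sigma > 0:
        plane = ndi.gaussian_filter(plane.astype(float), smooth_sigma)
    img = normalize_image(plane)
    if find_dish:
        img = extract_dish_mask(img, dish_cfg)
    return maybe_invert(img, invert_mode)
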
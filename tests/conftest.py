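"""Shared fixtures: all imagery is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cfuseg import PlateSpec, Segment, generate_plate


def segment_from_area(area: int, mean_intensity: float = 0.8, width: int = 100) -> Segment:
    """Fabricate a connected segment with an exact pixel count."""
    rows = area // width
    rem = area - rows * width
    h = rows + (2 if rem else 1)
    mask = np.zeros((h, width), dtype=bool)
    mask[:rows, :] = True
    if rem:
        mask[rows, :rem] = True
    if not rows:
        mask[0, :rem] = True
    seg = Segment.from_mask(mask)
    seg.mean_intensity = mean_intensity
    return seg


def disc_image(radius: float, size: int | None = None, fg: float = 0.9, bg: float = 0.1,
               noise_sd: float = 0.01, seed: int = 0):
    """Sharp-edged disc on a flat background; returns (raw image, truth mask)."""
    size = size or int(4 * radius) + 40
    yy, xx = np.mgrid[:size, :size].astype(float)
    d = np.hypot(yy - size / 2, xx - size / 2)
    truth = d <= radius
    rng = np.random.default_rng(seed)
    return bg + (fg - bg) * truth + rng.normal(0, noise_sd, (size, size)), truth


@pytest.fixture(scope="session")
def default_plate():
    """One deterministic mid-density plate with a two-colony clump."""
    spec = PlateSpec(seed=5, n_colonies=20, clump=(2, 0.3))
    img, truth, dish = generate_plate(spec)
    return spec, img, truth, dish


@pytest.fixture(scope="session")
def clean_plate():
    """Noise-free plate with well-separated colonies (no clump)."""
    spec = PlateSpec(seed=9, n_colonies=15, noise_sd=0.0, min_gap=8.0,
                     radius_range=(14.0, 24.0))
    img, truth, dish = generate_plate(spec)
    return spec, img, truth, dish
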
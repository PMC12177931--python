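"""Shared fixtures: hand-built mask geometries with known morphometrics."""

import numpy as np
import pytest
from hypothesis import settings

from patternoid.geometry import PixelCalibration

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")
from patternoid.pipeline import PatternoidMask


@pytest.fixture
def unit_cal():
    return PixelCalibration(1.0)


def blank_canvas(size=401):
    return np.zeros((size, size), dtype=bool)


def add_disk(pixels, cx, cy, r_px):
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    pixels |= np.hypot(xx - cx, yy - cy) <= r_px
    return pixels


def add_ray(pixels, cx, cy, angle_deg, r0_px, r1_px, half_width_px=2):
    """Straight radial bar from r0 to r1 at the given angle (axis-aligned angles stay exact)."""
    th = np.deg2rad(angle_deg)
    ux, uy = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    dx, dy = xx - cx, yy - cy
    along = dx * ux + dy * uy
    across = np.abs(-dx * uy + dy * ux)
    pixels |= (along >= r0_px) & (along <= r1_px) & (across <= half_width_px)
    return pixels


def mask_from(pixels, cx, cy, radius_um, pixel_size_um=1.0):
    return PatternoidMask(
        pixels=pixels,
        cal=PixelCalibration(pixel_size_um),
        cavity_center_px=(cx, cy),
        cavity_radius_um=radius_um,
    )


@pytest.fixture
def disk_mask(unit_cal):
    """Exact cavity disk, radius 50 um at 1 um/px: non-invasive only."""
    px = add_disk(blank_canvas(201), 100, 100, 50)
    return mask_from(px, 100, 100, 50.0)


@pytest.fixture
def three_ray_mask():
    """Disk + three well-separated straight rays: 3 roots, 3 tips."""
    px = add_disk(blank_canvas(401), 200, 200, 50)
    for ang in (0, 120, 240):
        add_ray(px, 200, 200, ang, 45, 150)
    return mask_from(px, 200, 200, 50.0)


@pytest.fixture
def single_ray_mask():
    """Disk + one ray ending exactly 150 um beyond the boundary."""
    px = add_disk(blank_canvas(451), 225, 225, 50)
    add_ray(px, 225, 225, 0, 45, 200)
    return mask_from(px, 225, 225, 50.0)
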
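"""Image pipeline: raw confocal stacks to calibrated binary masks.

Mirrors the four-step batch macro used for endpoint analysis:
maximum z-projection, cropping, denoising, and binarization.  The
binary mask, together with the cavity centre/radius it was acquired
around, is the unit every morphometric operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .geometry import GeometryError, PixelCalibration

__all__ = [
    "PipelineError",
    "ImageStack",
    "PatternoidMask",
    "max_projection",
    "sum_projection",
    "std_projection",
    "denoise",
    "binarize",
    "crop_to_window",
    "read_stack",
    "write_mask",
    "read_mask",
]


class PipelineError(ValueError):
    """Invalid image-pipeline input."""


@dataclass
class ImageStack:
    """3D intensity grid ``(z, y, x)`` with its calibration."""

    voxels: np.ndarray
    cal: PixelCalibration
    z_step_um: float = 2.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise PipelineError("stack must be a non-empty 3D (z, y, x) array")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise PipelineError("intensities must be finite and >= 0")


@dataclass
class PatternoidMask:
    """Calibrated 2D binary mask of one patternoid.

    ``cavity_center_px`` is ``(cx, cy)`` in pixel coordinates (x right,
    y down, pixel centres at integers); the cavity circle must lie fully
    inside the grid.
    """

    pixels: np.ndarray
    cal: PixelCalibration
    cavity_center_px: tuple[float, float]
    cavity_radius_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise PipelineError("mask must be 2D")
        cx, cy = self.cavity_center_px
        r_px = self.cavity_radius_um / self.cal.pixel_size_um
        h, w = self.pixels.shape
        if cx - r_px < -0.5 or cy - r_px < -0.5 or cx + r_px > w - 0.5 or cy + r_px > h - 0.5:
            raise PipelineError("cavity circle must lie inside the mask grid")

    def radial_distance_um(self) -> np.ndarray:
        """Per-pixel Euclidean distance from the cavity centre, in um."""
        cx, cy = self.cavity_center_px
        yy, xx = np.mgrid[0 : self.pixels.shape[0], 0 : self.pixels.shape[1]]
        return np.hypot(xx - cx, yy - cy) * self.cal.pixel_size_um


def _as_voxels(stack) -> np.ndarray:
    v = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if v.ndim != 3 or v.size == 0:
        raise PipelineError("expected a non-empty 3D stack")
    return v


def max_projection(stack) -> np.ndarray:
    """Per-pixel maximum across z."""
    return _as_voxels(stack).max(axis=0)


def sum_projection(stack) -> np.ndarray:
    """Per-pixel sum across z."""
    return _as_voxels(stack).sum(axis=0)


def std_projection(stack) -> np.ndarray:
    """Per-pixel population standard deviation across z (zero for one slice)."""
    return _as_voxels(stack).std(axis=0, ddof=0)


def denoise(image: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Median filter with a circular footprint; ``radius_px=0`` is the identity."""
    if radius_px < 0:
        raise PipelineError("radius_px must be >= 0")
    image = np.asarray(image, dtype=float)
    if radius_px == 0:
        return image.copy()
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    footprint = (xx * xx + yy * yy) <= radius_px * radius_px
    return ndi.median_filter(image, footprint=footprint, mode="nearest")


def binarize(image: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binary mask: pixel true iff intensity > threshold.

    ``method="otsu"`` picks the threshold by between-class variance
    maximisation on a 256-bin histogram; ``method="fixed"`` uses the
    supplied threshold (the "minor manual adjustment" escape hatch).
    """
    image = np.asarray(image, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise PipelineError("fixed binarization requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(image) == 0:
            raise PipelineError("otsu threshold undefined for a constant image")
        thr = float(threshold_otsu(image, nbins=256))
    else:
        raise PipelineError(f"unknown binarization method {method!r}")
    return image > thr


def crop_to_window(
    grid: np.ndarray,
    center_px: tuple[float, float],
    half_width_um: float,
    cal: PixelCalibration,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Crop a square window of ``2*half_width_um`` around ``center_px``.

    Returns the sub-grid and the centre coordinates re-expressed in the
    cropped frame.  The window is clipped to the grid; a window fully
    outside raises.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise PipelineError("expected a 2D grid")
    cx, cy = center_px
    half_px = int(round(half_width_um / cal.pixel_size_um))
    x0, x1 = int(round(cx)) - half_px, int(round(cx)) + half_px + 1
    y0, y1 = int(round(cy)) - half_px, int(round(cy)) + half_px + 1
    h, w = grid.shape
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        raise PipelineError("crop window lies fully outside the grid")
    x0c, y0c = max(x0, 0), max(y0, 0)
    cropped = grid[y0c : min(y1, h), x0c : min(x1, w)]
    return cropped, (cx - x0c, cy - y0c)


def read_stack(path, cal: PixelCalibration, z_step_um: float = 2.0) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`."""
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    return ImageStack(voxels=np.asarray(voxels, dtype=float), cal=cal, z_step_um=z_step_um)


def write_mask(path, mask: PatternoidMask) -> None:
    """Write a mask as 8-bit TIFF (0/255) with its metadata in the description."""
    import json

    meta = {
        "pixel_size_um": mask.cal.pixel_size_um,
        "cavity_center_px": list(mask.cavity_center_px),
        "cavity_radius_um": mask.cavity_radius_um,
    }
    tifffile.imwrite(
        Path(path),
        (mask.pixels.astype(np.uint8) * 255),
        description=json.dumps(meta),
    )


def read_mask(path) -> PatternoidMask:
    """Read a mask written by :func:`write_mask`, restoring its metadata."""
    import json

    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        desc = page.tags["ImageDescription"].value
    meta = json.loads(desc)
    return PatternoidMask(
        pixels=data > 0,
        cal=PixelCalibration(meta["pixel_size_um"]),
        cavity_center_px=tuple(meta["cavity_center_px"]),
        cavity_radius_um=meta["cavity_radius_um"],
    )
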
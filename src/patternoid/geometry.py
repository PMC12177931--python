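"""Physical geometry of the collagen microcavity array.

Every downstream measurement is expressed in micrometres after pixel
calibration, so that images acquired at different magnifications
(e.g. 0.569 and 2.27 um/px) yield directly comparable morphometrics.

Conventions
-----------
* 2D coordinates are ``(x, y)`` in micrometres unless suffixed ``_px``.
* Pixel grids are indexed ``[y, x]`` with the origin at the top-left
  pixel; pixel centres sit at integer coordinates.
* A pixel counts as inside a circle iff its centre is inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "CavityGeometry",
    "ArrayLayout",
    "PixelCalibration",
    "projected_cavity_area",
    "array_centers",
    "um_to_px",
    "px_to_um",
]


class GeometryError(ValueError):
    """Invalid physical geometry or calibration."""


@dataclass(frozen=True)
class CavityGeometry:
    """Cylindrical microcavity moulded into the collagen gel.

    Defaults follow the stamp used throughout: 100 um diameter,
    200 um depth, 600 um centre-to-centre pitch.  The depth is
    metadata only -- all analysis operates on 2D projections.
    """

    diameter_um: float = 100.0
    height_um: float = 200.0
    pitch_um: float = 600.0

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise GeometryError(f"diameter_um must be > 0, got {self.diameter_um}")
        if not self.height_um > 0:
            raise GeometryError(f"height_um must be > 0, got {self.height_um}")
        if self.pitch_um < self.diameter_um:
            raise GeometryError(
                f"pitch_um ({self.pitch_um}) must be >= diameter_um ({self.diameter_um})"
            )

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def projected_area_um2(self) -> float:
        """Projected (top-view) area of the circular cavity, recomputed."""
        return math.pi * (self.diameter_um / 2.0) ** 2


def projected_cavity_area(geometry: CavityGeometry) -> float:
    """Projected area of the circular cavity in um^2.

    For the default 100 um cavity this is 7853.98... um^2, reported as
    7854 um^2 at display precision; rounding happens only at reporting
    time.
    """
    return geometry.projected_area_um2


@dataclass(frozen=True)
class ArrayLayout:
    """Regular grid of microcavities stamped into one gel (default 25 x 26)."""

    rows: int = 25
    cols: int = 26
    origin_um: tuple[float, float] = (0.0, 0.0)
    cavity: CavityGeometry = field(default_factory=CavityGeometry)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GeometryError(f"rows and cols must be >= 1, got {self.rows}x{self.cols}")

    @property
    def n_cavities(self) -> int:
        return self.rows * self.cols


def array_centers(layout: ArrayLayout) -> np.ndarray:
    """Cavity centre coordinates in um, shape ``(rows*cols, 2)`` as ``(x, y)``.

    Row-major order: index ``i = row*cols + col``.
    """
    pitch = layout.cavity.pitch_um
    ox, oy = layout.origin_um
    rr, cc = np.meshgrid(np.arange(layout.rows), np.arange(layout.cols), indexing="ij")
    centers = np.column_stack([ox + cc.ravel() * pitch, oy + rr.ravel() * pitch])
    return centers.astype(float)


@dataclass(frozen=True)
class PixelCalibration:
    """Isotropic pixel size in um/px."""

    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise GeometryError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")


def um_to_px(value_um, cal: PixelCalibration):
    """Convert a length (or array of lengths) from um to pixels."""
    return np.asarray(value_um, dtype=float) / cal.pixel_size_um if np.ndim(value_um) else float(value_um) / cal.pixel_size_um


def px_to_um(value_px, cal: PixelCalibration):
    """Inverse of :func:`um_to_px`."""
    return np.asarray(value_px, dtype=float) * cal.pixel_size_um if np.ndim(value_px) else float(value_px) * cal.pixel_size_um
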
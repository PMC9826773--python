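"""Core image containers: HU slice stacks and regions of interest.

All spatial conventions used throughout the package are fixed here:

* voxels are indexed ``(slice, row, col)``; row corresponds to the y axis,
  col to the x axis;
* indices are 0-based; the physical position of a pixel *center* along an
  axis is ``(index + 0.5) * spacing`` in mm;
* pixel spacings are in mm and analysis always operates on floating-point
  Hounsfield units (HU), whatever the storage format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class GeometryError(ValueError):
    """An ROI or insert does not fit the image geometry."""


@dataclass
class ImageStack:
    """A stack of axial CT slices in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, converted to float64 on construction.
    pixel_spacing_x, pixel_spacing_y : float
        In-plane pixel sizes Δx (along columns) and Δy (along rows), mm.
    slice_thickness : float
        Nominal reconstructed slice thickness, mm.
    slice_increment : float
        Spacing between consecutive slice positions, mm.
    meta : dict
        Free-form provenance (e.g. ``energy_keV``, ``recon_level``,
        ``version_tag``, ``seed``, ground-truth generator parameters).
    """

    voxels: np.ndarray
    pixel_spacing_x: float
    pixel_spacing_y: float
    slice_thickness: float = 0.5
    slice_increment: float = 0.5
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3D (slice, row, col); got shape {self.voxels.shape}"
            )
        if not (self.pixel_spacing_x > 0 and self.pixel_spacing_y > 0):
            raise GeometryError("pixel spacings must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice(self, index: int) -> np.ndarray:
        return self.voxels[index]

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of pixel centers for one slice, mm."""
        n_rows, n_cols = self.voxels.shape[1:]
        y = (np.arange(n_rows) + 0.5) * self.pixel_spacing_y
        x = (np.arange(n_cols) + 0.5) * self.pixel_spacing_x
        return y, x


@dataclass(frozen=True)
class SquareROI:
    """Axis-aligned square ROI given by its center pixel and side length."""

    center_row: int
    center_col: int
    side_pixels: int

    def __post_init__(self) -> None:
        if self.side_pixels < 2:
            raise GeometryError("side_pixels must be >= 2")

    def bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open pixel bounds."""
        half = self.side_pixels // 2
        r0 = self.center_row - half
        c0 = self.center_col - half
        return r0, r0 + self.side_pixels, c0, c0 + self.side_pixels

    def validate(self, stack: ImageStack) -> None:
        r0, r1, c0, c1 = self.bounds()
        _, n_rows, n_cols = stack.shape
        if r0 < 0 or c0 < 0 or r1 > n_rows or c1 > n_cols:
            raise GeometryError(
                f"square ROI {self} exceeds image bounds ({n_rows}x{n_cols})"
            )

    def extract(self, stack: ImageStack, slice_index: int) -> np.ndarray:
        self.validate(stack)
        r0, r1, c0, c1 = self.bounds()
        return stack.voxels[slice_index, r0:r1, c0:c1]


@dataclass(frozen=True)
class CircularROI:
    """Circular ROI; center may be fractional pixel coordinates, radius in mm."""

    center_row: float
    center_col: float
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise GeometryError("radius_mm must be positive")

    def mask(self, stack: ImageStack) -> np.ndarray:
        """Boolean mask of pixels whose centers lie within radius_mm."""
        _, n_rows, n_cols = stack.shape
        rr, cc = np.meshgrid(
            np.arange(n_rows), np.arange(n_cols), indexing="ij"
        )
        dy = (rr - self.center_row) * stack.pixel_spacing_y
        dx = (cc - self.center_col) * stack.pixel_spacing_x
        return dy * dy + dx * dx <= self.radius_mm**2

    def validate(self, stack: ImageStack) -> None:
        _, n_rows, n_cols = stack.shape
        ry = self.radius_mm / stack.pixel_spacing_y
        rx = self.radius_mm / stack.pixel_spacing_x
        if (
            self.center_row - ry < -0.5
            or self.center_col - rx < -0.5
            or self.center_row + ry > n_rows - 0.5
            or self.center_col + rx > n_cols - 0.5
        ):
            raise GeometryError(f"circular ROI {self} exceeds image bounds")


def mean_hu(stack: ImageStack, roi: CircularROI, slice_index: int) -> float:
    """Mean HU over pixels whose centers fall inside a circular ROI.

    The pixel-in-ROI rule is center-within-radius (no area weighting),
    matching common clinical ROI tools.
    """
    roi.validate(stack)
    mask = roi.mask(stack)
    if not mask.any():
        raise GeometryError("circular ROI contains no pixel centers")
    return float(stack.voxels[slice_index][mask].mean())
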
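"""Regions of interest: circles and polygons, masks, areas, bounding boxes.

Coordinate convention (fixed across the package): 0-based pixel coordinates,
x is the column axis, y the row axis, and a pixel's center sits at integer
coordinates.  ROI membership is boundary-inclusive: a pixel belongs to the
ROI when its center lies inside or on the boundary.  ROI positions are
real-valued (the tracker outputs sub-pixel centers) and masks are
re-rasterized from the analytic geometry every frame, so no rounding error
accumulates over a sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "CircleRoi",
    "PolygonRoi",
    "Roi",
    "BoundingBox",
    "roi_mask",
    "roi_area",
    "mean_intensity",
    "circumscribed_bbox",
    "translate_roi",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle: top-left corner (x, y), extents (w, h).

    Covers the half-open region [x, x+w) x [y, y+h).
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError("bounding box extents must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.w, self.h)


@dataclass(frozen=True)
class CircleRoi:
    """Circular ROI: center (cx, cy) and radius, all in pixels."""

    cx: float
    cy: float
    r: float
    id: str = "C1"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cx) and np.isfinite(self.cy) and np.isfinite(self.r)):
            raise ValueError("circle parameters must be finite")
        if self.r <= 0:
            raise ValueError("circle radius must be positive")


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PolygonRoi:
    """Simple polygon ROI from an ordered vertex list [(x, y), ...]."""

    vertices: tuple[tuple[float, float], ...]
    id: str = "R1"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        arr = np.asarray(verts, dtype=np.float64)
        if arr.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not np.all(np.isfinite(arr)):
            raise ValueError("polygon vertices must be finite")
        if abs(_shoelace(arr)) == 0.0:
            raise ValueError("degenerate polygon: vertices are collinear")
        object.__setattr__(self, "vertices", verts)

    @property
    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=np.float64)


Roi = Union[CircleRoi, PolygonRoi]


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test, boundary-inclusive, vectorized."""
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: point on segment [v1, v2]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.minimum(x1, x2) - 1e-9 <= px)
            & (px <= np.maximum(x1, x2) + 1e-9)
            & (np.minimum(y1, y2) - 1e-9 <= py)
            & (py <= np.maximum(y1, y2) + 1e-9)
        )
        on_edge |= (np.abs(cross) < 1e-9 * max(1.0, abs(x2 - x1) + abs(y2 - y1))) & within
        # even-odd ray crossing (ray to +x); half-open in y to count shared
        # vertices exactly once; horizontal edges never satisfy the y test
        with np.errstate(divide="ignore", invalid="ignore"):
            crosses = ((y1 > py) != (y2 > py)) & (
                px < x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            )
        inside ^= crosses
    return inside | on_edge


def roi_mask(roi: Roi, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ROI to a boolean mask over an image of ``image_shape``.

    A pixel is True iff its center (integer x = column, y = row) lies inside
    or on the ROI boundary.  An ROI entirely outside the image produces an
    all-False mask and a warning, not an error.
    """
    rows, cols = image_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("image shape must be positive")
    yy, xx = np.mgrid[0:rows, 0:cols]
    if isinstance(roi, CircleRoi):
        mask = (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= roi.r**2
    elif isinstance(roi, PolygonRoi):
        mask = _points_in_polygon(
            xx.astype(np.float64), yy.astype(np.float64), roi.vertex_array
        )
    else:
        raise TypeError(f"not an ROI: {roi!r}")
    if not mask.any():
        warnings.warn(
            f"ROI {roi.id!r} lies entirely outside the {rows}x{cols} image",
            stacklevel=2,
        )
    return mask


def roi_area(roi: Roi, pixel_scale_cm: float = 1.0) -> float:
    """Analytic ROI area in cm^2 given the physical pixel pitch (cm/pixel).

    Circle: pi r^2 * scale^2; polygon: shoelace formula * scale^2.
    """
    if pixel_scale_cm <= 0:
        raise ValueError("pixel_scale_cm must be positive")
    if isinstance(roi, CircleRoi):
        area_px = np.pi * roi.r**2
    elif isinstance(roi, PolygonRoi):
        area_px = abs(_shoelace(roi.vertex_array))
    else:
        raise TypeError(f"not an ROI: {roi!r}")
    return float(area_px * pixel_scale_cm**2)


def mean_intensity(image: np.ndarray, roi: Roi) -> float:
    """Arithmetic mean of image values at the ROI's mask-true pixels."""
    image = np.asarray(image, dtype=np.float64)
    mask = roi_mask(roi, image.shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.id!r} covers no pixels of the image")
    return float(image[mask].mean())


def circumscribed_bbox(roi: Roi) -> BoundingBox:
    """Minimal axis-aligned rectangle containing the ROI.

    This circumscribed rectangle is what the tracker follows; its center
    coincides with the ROI center for circles.
    """
    if isinstance(roi, CircleRoi):
        return BoundingBox(roi.cx - roi.r, roi.cy - roi.r, 2 * roi.r, 2 * roi.r)
    if isinstance(roi, PolygonRoi):
        v = roi.vertex_array
        x0, y0 = v.min(axis=0)
        x1, y1 = v.max(axis=0)
        return BoundingBox(float(x0), float(y0), float(x1 - x0), float(y1 - y0))
    raise TypeError(f"not an ROI: {roi!r}")


def translate_roi(roi: Roi, dx: float, dy: float) -> Roi:
    """Return the ROI rigidly shifted by (dx, dy); shape and area unchanged."""
    if isinstance(roi, CircleRoi):
        return replace(roi, cx=roi.cx + dx, cy=roi.cy + dy)
    if isinstance(roi, PolygonRoi):
        return replace(
            roi, vertices=tuple((x + dx, y + dy) for x, y in roi.vertices)
        )
    raise TypeError(f"not an ROI: {roi!r}")
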
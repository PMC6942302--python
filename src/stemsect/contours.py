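"""Closed-contour shape representation shared by every detected object.

All detected structures (the stem boundary, zone boundaries, vascular
bundles) are represented uniformly as ordered closed polygons in pixel
coordinates.  Coordinates are (row, col), 0-based, row 0 at the top.
Polygon vertices produced from binary masks lie on the half-pixel
marching-squares lattice (the 0.5 iso-level between foreground and
background pixel centers), so the polygon area of an axis-aligned block
equals its pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, measure
from shapely.geometry import Polygon


class NoObjectError(ValueError):
    """Raised when a binary mask contains no usable object."""


@dataclass(frozen=True)
class ContourShape:
    """Ordered closed polygon with its filled-region summary.

    Parameters
    ----------
    points : (N, 2) float array
        Vertices as (row, col); the polygon is implicitly closed.
    area_px : int
        Pixel count of the enclosed filled region.
    centroid : (float, float)
        (row, col) centroid of the filled region.
    """

    points: np.ndarray
    area_px: int
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("a contour needs at least 3 (row, col) points")
        if self.area_px <= 0:
            raise ValueError("contour encloses no area")
        object.__setattr__(self, "points", pts)

    def to_polygon(self) -> Polygon:
        """Shapely polygon in (x=col, y=row) axes; repaired if needed."""
        poly = Polygon(self.points[:, ::-1])
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


def largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Boolean mask of the largest connected foreground component.

    ``connectivity`` follows scikit-image: 1 = 4-connected, 2 = 8-connected.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("empty mask: no object")
    labels = measure.label(mask, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def boundary_polygon(filled: np.ndarray) -> np.ndarray:
    """Outer boundary polygon (row, col) of a filled binary region.

    Marching squares on the zero-padded mask; the contour enclosing the
    largest signed area is the outer boundary.
    """
    padded = np.pad(np.asarray(filled, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if not contours:
        raise NoObjectError("no boundary found")

    def shoelace(c: np.ndarray) -> float:
        r, col = c[:, 0], c[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(col, -1)) - np.dot(col, np.roll(r, -1)))

    best = max(contours, key=shoelace)
    return best - 1.0  # undo padding offset


def contour_from_mask(mask: np.ndarray, connectivity: int = 2) -> ContourShape:
    """Extract the outer contour of the largest component, holes filled."""
    comp = largest_component(mask, connectivity=connectivity)
    filled = ndimage.binary_fill_holes(comp)
    pts = boundary_polygon(filled)
    area = int(filled.sum())
    rr, cc = np.nonzero(filled)
    return ContourShape(points=pts, area_px=area,
                        centroid=(float(rr.mean()), float(cc.mean())))


def contour_from_filled(filled: np.ndarray) -> ContourShape:
    """Like :func:`contour_from_mask` but trusts ``filled`` as the region."""
    filled = np.asarray(filled, dtype=bool)
    if not filled.any():
        raise NoObjectError("empty region")
    pts = boundary_polygon(filled)
    rr, cc = np.nonzero(filled)
    return ContourShape(points=pts, area_px=int(filled.sum()),
                        centroid=(float(rr.mean()), float(cc.mean())))


def mask_from_contour(contour: ContourShape, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the filled polygon onto a grid of the given shape."""
    rr, cc = draw.polygon(contour.points[:, 0], contour.points[:, 1], shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out
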
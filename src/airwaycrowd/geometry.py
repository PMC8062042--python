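"""Ellipse primitives for crowd airway annotations.

Workers outline an airway by drawing two ellipses in a 500x500-pixel image
slice: one around the lumen (inner boundary) and one around the outer wall
boundary.  This module holds the ellipse type, the image-frame metadata that
maps pixels to millimetres, and the geometric predicates the validity filter
and the airway measures are built on.

Coordinate convention: raster convention with the origin at the top-left,
x increasing rightward and y increasing downward.  "Top-right corner"
therefore means large x, small y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "EllipseAnnotation",
    "ImageFrame",
    "InvalidGeometryError",
    "InvalidMeasureError",
    "ellipse_area",
    "equivalent_diameter",
    "ellipse_polygon",
    "ellipses_overlap",
    "is_corner_marker",
]

#: Number of vertices used to discretize an ellipse boundary for the
#: polygonal overlap test.  Exactness is not required: real annotations are
#: far from tangency, so a fine polygon is ample.
OVERLAP_POLYGON_VERTICES = 256


class InvalidGeometryError(ValueError):
    """An ellipse violates its geometric invariants."""


class InvalidMeasureError(ValueError):
    """A derived measure received an out-of-domain argument."""


def _normalize_rotation(theta: float) -> float:
    """Map an angle in radians to [0, pi); an ellipse has period pi."""
    r = float(theta) % math.pi
    return 0.0 if r >= math.pi else r  # tiny negatives wrap to pi in float


@dataclass(frozen=True)
class EllipseAnnotation:
    """One drawn ellipse in image-pixel coordinates.

    Parameters
    ----------
    center_x, center_y : float
        Center in pixels (raster convention, origin top-left).
    semi_axis_a, semi_axis_b : float
        Semi-axis lengths in pixels; both must be strictly positive.
    rotation : float
        Orientation in radians; normalized to [0, pi) on construction.
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_axis_a > 0 and self.semi_axis_b > 0):
            raise InvalidGeometryError(
                f"semi-axes must be positive, got "
                f"({self.semi_axis_a}, {self.semi_axis_b})"
            )
        object.__setattr__(self, "rotation", _normalize_rotation(self.rotation))

    @property
    def mean_semi_axis(self) -> float:
        return 0.5 * (self.semi_axis_a + self.semi_axis_b)

    def is_circle(self, rel_tol: float = 1e-9) -> bool:
        """True if the two semi-axes agree to within ``rel_tol`` (relative)."""
        a, b = self.semi_axis_a, self.semi_axis_b
        return abs(a - b) <= rel_tol * max(a, b)


@dataclass(frozen=True)
class ImageFrame:
    """Annotation image geometry and the pixel-to-mm scale.

    The default scale follows slices of 50x50 voxels (0.5508 mm in-plane
    voxel size) upsampled to 500x500 pixels: 0.5508 * 50 / 500 mm per pixel.
    """

    width: float = 500.0
    height: float = 500.0
    mm_per_pixel: float = 0.05508

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.mm_per_pixel <= 0:
            raise InvalidGeometryError("frame dimensions and scale must be positive")

    @property
    def mm2_per_pixel2(self) -> float:
        return self.mm_per_pixel ** 2


def ellipse_area(e: EllipseAnnotation) -> float:
    """Area of an ellipse in pixels^2: pi * a * b (rotation-invariant)."""
    return math.pi * e.semi_axis_a * e.semi_axis_b


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: 2*sqrt(area/pi).

    Crowd workers draw (near-circular) ellipses but the expert records only
    areas, so crowd-vs-expert diameter comparisons assume circular airways
    and derive every diameter from an area through this function.  Unit
    preserving: pixel^2 in, pixels out; mm^2 in, mm out.
    """
    if area < 0:
        raise InvalidMeasureError(f"area must be non-negative, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def ellipse_polygon(
    e: EllipseAnnotation, n_vertices: int = OVERLAP_POLYGON_VERTICES
) -> Polygon:
    """Discretize the ellipse boundary to an ``n_vertices``-gon."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cos_r, sin_r = math.cos(e.rotation), math.sin(e.rotation)
    x_local = e.semi_axis_a * np.cos(t)
    y_local = e.semi_axis_b * np.sin(t)
    x = e.center_x + cos_r * x_local - sin_r * y_local
    y = e.center_y + sin_r * x_local + cos_r * y_local
    return Polygon(np.column_stack([x, y]))


def ellipses_overlap(e1: EllipseAnnotation, e2: EllipseAnnotation) -> bool:
    """True iff the ellipse interiors intersect with positive area.

    Containment counts as overlap (the usual valid annotation has the lumen
    ellipse fully inside the wall ellipse).  Implemented as intersection of
    256-vertex boundary polygons; boundary-only touching does not count.
    """
    p1, p2 = ellipse_polygon(e1), ellipse_polygon(e2)
    if not p1.intersects(p2):
        return False
    return p1.intersection(p2).area > 0.0


def is_corner_marker(
    e: EllipseAnnotation,
    frame: ImageFrame,
    corner_fraction: float = 0.2,
    size_fraction: float = 0.1,
) -> bool:
    """Is this ellipse the "no airway visible" top-right corner marker?

    Workers flag an image without a visible airway by placing a small circle
    in the top-right corner.  The marker is recognized when the center lies
    in the top-right ``corner_fraction`` x ``corner_fraction`` region of the
    frame and the mean semi-axis is below ``size_fraction`` of the frame
    width.  Both fractions are configuration: no canonical values exist, the
    defaults (20% corner region, 10% size) are this package's choice.
    """
    in_corner = (
        e.center_x >= frame.width * (1.0 - corner_fraction)
        and e.center_y <= frame.height * corner_fraction
    )
    small = e.mean_semi_axis < size_fraction * frame.width
    return in_corner and small
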
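"""Geometric data model for slice-wise organ contours.

Contours live in patient coordinates (mm) throughout: a contour is a stack
of closed planar polygons, one per axial slice, each stored as an ordered
sequence of (x, y, z) boundary points.  This mirrors how radiotherapy
structure sets represent organs, and it is the representation on which the
boundary-point similarity metrics in :mod:`contourhsc.metrics` operate.

Polygons are stored *open* — the first vertex is not repeated at the end;
closure is implicit.  Vertex order is normalized to counter-clockwise on
construction (the original orientation is recorded for round-trip writing),
so signed-area conventions never leak into downstream code.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as _Polygon

from .errors import GeometryError

#: two points on one slice must share z to within this (mm)
Z_COPLANAR_TOL = 1e-9


@dataclass(frozen=True)
class BoundaryPoint:
    """A single boundary point: an (x, y, z) triplet in patient mm."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise GeometryError(f"non-finite boundary point coordinate: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class SliceContour:
    """One closed, simple planar polygon at a fixed axial position.

    Parameters
    ----------
    points : array-like, shape (n, 3)
        Ordered boundary points.  All must share the same z to within
        ``Z_COPLANAR_TOL``; the first point must not be repeated at the end.

    Notes
    -----
    The polygon must be simple (non-self-intersecting) with nonzero area.
    Vertex order is normalized to counter-clockwise; ``was_clockwise``
    records the ingested orientation.
    """

    __slots__ = ("_points", "_z", "was_clockwise", "_shapely")

    def __init__(self, points):
        pts = np.asarray(
            [p.as_array() if isinstance(p, BoundaryPoint) else p for p in points],
            dtype=float,
        )
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"expected (n, 3) points, got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise GeometryError("a slice contour needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("contour contains non-finite coordinates")
        z = pts[0, 2]
        if np.max(np.abs(pts[:, 2] - z)) > Z_COPLANAR_TOL:
            raise GeometryError("contour points are not coplanar in z")
        if np.allclose(pts[0, :2], pts[-1, :2]):
            raise GeometryError(
                "first point repeated at the end; contours are stored open"
            )
        signed = _signed_area(pts[:, 0], pts[:, 1])
        if abs(signed) < 1e-12:
            raise GeometryError("degenerate contour: zero area")
        poly = _Polygon(pts[:, :2])
        if not poly.is_valid:
            raise GeometryError("contour polygon is not simple/valid")
        self.was_clockwise = signed < 0
        if self.was_clockwise:
            # reverse while keeping the original first vertex first
            pts = np.roll(pts[::-1], 1, axis=0)
            poly = _Polygon(pts[:, :2])
        self._points = pts
        self._points.setflags(write=False)
        self._z = float(z)
        self._shapely = poly

    # -- basic accessors ---------------------------------------------------
    @property
    def z(self) -> float:
        return self._z

    @property
    def points(self) -> np.ndarray:
        """Read-only (n, 3) array of boundary points, counter-clockwise."""
        return self._points

    @property
    def xy(self) -> np.ndarray:
        return self._points[:, :2]

    @property
    def n_points(self) -> int:
        return self._points.shape[0]

    def boundary_points(self) -> list[BoundaryPoint]:
        return [BoundaryPoint(*p) for p in self._points]

    @property
    def polygon(self) -> _Polygon:
        """The slice as a shapely polygon (implicitly closed)."""
        return self._shapely

    # -- geometry ----------------------------------------------------------
    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.xy, self.xy[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def scaled(self, factor: float, about: np.ndarray | None = None) -> "SliceContour":
        """Similarity transform in-plane about ``about`` (default: centroid)."""
        if about is None:
            about = centroid(self).as_array()[:2]
        about = np.asarray(about, dtype=float)[:2]
        xy = about + factor * (self.xy - about)
        pts = np.column_stack([xy, np.full(self.n_points, self._z)])
        return SliceContour(pts)

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "SliceContour":
        return SliceContour(self._points + np.array([dx, dy, dz]))

    def __repr__(self):
        return f"SliceContour(z={self._z:g}, n_points={self.n_points})"


def _signed_area(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(c: SliceContour) -> float:
    """Absolute enclosed area of a slice contour in mm²."""
    return float(c.polygon.area)


def centroid(c: SliceContour) -> BoundaryPoint:
    """Area-weighted polygon centroid, at the slice's z."""
    p = c.polygon.centroid
    return BoundaryPoint(p.x, p.y, c.z)


def resample(c: SliceContour, n: int) -> SliceContour:
    """Resample a contour to ``n`` points at equal arc-length spacing.

    The first output point coincides with the original first vertex; the
    walk proceeds in the contour's (counter-clockwise) vertex order along
    the closed boundary.
    """
    if n < 3:
        raise ValueError(f"resample needs n >= 3, got {n}")
    closed = np.vstack([c.xy, c.xy[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * (total / n)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    pts = np.column_stack([x, y, np.full(n, c.z)])
    return SliceContour(pts)


@dataclass
class Structure:
    """A named organ contour: slices ordered by strictly increasing z.

    ``slice_thickness`` is the nominal axial spacing in mm; it drives slice
    pairing between two structures (z values are considered the same plane
    when within half a slice thickness).
    """

    name: str
    slices: list[SliceContour]
    slice_thickness: float = 3.0

    def __post_init__(self):
        if self.slice_thickness <= 0:
            raise GeometryError("slice_thickness must be positive")
        self.slices = sorted(self.slices, key=lambda s: s.z)
        zs = self.z_values
        if len(zs) > 1 and np.min(np.diff(zs)) <= Z_COPLANAR_TOL:
            raise GeometryError("duplicate or non-increasing slice z values")

    @property
    def z_values(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def total_points(self) -> int:
        """Total boundary-point count over all slices (the HSC denominator
        when this structure is the final contour)."""
        return sum(s.n_points for s in self.slices)

    def point_array(self) -> np.ndarray:
        """All boundary points stacked into one (N, 3) array."""
        if not self.slices:
            return np.empty((0, 3))
        return np.vstack([s.points for s in self.slices])

    def bounds(self) -> tuple[float, float, float, float]:
        """In-plane bounding box (xmin, ymin, xmax, ymax) over all slices."""
        if not self.slices:
            raise GeometryError("empty structure has no bounds")
        boxes = np.array([s.polygon.bounds for s in self.slices])
        return (
            float(boxes[:, 0].min()),
            float(boxes[:, 1].min()),
            float(boxes[:, 2].max()),
            float(boxes[:, 3].max()),
        )

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "Structure":
        return Structure(
            self.name,
            [s.translated(dx, dy, dz) for s in self.slices],
            self.slice_thickness,
        )

    def with_name(self, name: str) -> "Structure":
        return dataclasses.replace(self, name=name, slices=list(self.slices))

    def __repr__(self):
        return (
            f"Structure({self.name!r}, n_slices={self.n_slices}, "
            f"total_points={self.total_points}, dz={self.slice_thickness:g})"
        )
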
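"""Planar polygon primitives shared by every pipeline stage.

All coordinates are in millimetres; angles are in degrees, counter-clockwise
positive.  A contour is a dense closed polyline (the last vertex connects
back to the first) approximating a hand-drawn or traced tissue boundary.

Frames
------
``image``
    The slice's own frame: origin at the lower-left of the converted image
    (pixel data are y-down; contours are flipped to y-up on creation so that
    areas and rotations follow the usual mathematical convention).
``base``
    The frame of the base (reference) probe view, shared by all slices after
    registration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence, Tuple, Union

import numpy as np
import shapely

Point2 = Tuple[float, float]

FRAME_IMAGE = "image"
FRAME_BASE = "base"
_FRAMES = (FRAME_IMAGE, FRAME_BASE)


class GeometryError(ValueError):
    """Base class for contour/pose errors."""


class InvalidContourError(GeometryError):
    """Contour cannot be built: too few points, non-finite, self-intersecting."""


class DegenerateContourError(GeometryError):
    """Contour enclosing (numerically) zero area where positive area is required."""


# ---------------------------------------------------------------------------
# Raw-vertex operations (arrays of shape (N, 2))
# ---------------------------------------------------------------------------

def signed_area(points: Union[np.ndarray, Sequence[Point2]]) -> float:
    """Shoelace signed area of a closed polyline (positive for CCW order)."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise InvalidContourError("signed_area needs at least 3 points of shape (N, 2)")
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def area_centroid(points: Union[np.ndarray, Sequence[Point2]]) -> Tuple[float, float]:
    """Area-weighted centroid of the region enclosed by a closed polyline.

    This is the centroid of the enclosed lamina, not the vertex mean, and is
    invariant to the traversal direction of the boundary.
    """
    p = np.asarray(points, dtype=float)
    a = signed_area(p)
    if abs(a) < 1e-12:
        raise DegenerateContourError(
            f"zero-area contour (signed area {a:g} mm^2) has no centroid"
        )
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy


def _dedupe_closed(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop consecutive duplicate vertices, including the wrap-around pair."""
    p = np.asarray(points, dtype=float)
    if len(p) == 0:
        return p
    keep = np.ones(len(p), dtype=bool)
    d = np.linalg.norm(p - np.roll(p, 1, axis=0), axis=1)
    keep[1:] = d[1:] > tol
    out = p[keep]
    if len(out) > 1 and np.linalg.norm(out[0] - out[-1]) <= tol:
        out = out[:-1]
    return out


# ---------------------------------------------------------------------------
# Contour
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Contour2D:
    """Closed planar boundary of one structure, stored counter-clockwise.

    Parameters
    ----------
    label : str
        Structure identifier (muscle name, phantom layer, ...).
    points : (N, 2) array of float, mm
        Ordered vertices; the polygon is implicitly closed.  Consecutive
        duplicates are removed on construction and the winding is normalized
        to counter-clockwise (positive signed area).  Remaining
        self-intersections are an error, not silently repaired.
    frame : {"image", "base"}
    """

    label: str
    points: np.ndarray
    frame: str = FRAME_IMAGE

    def __post_init__(self):
        pts = _dedupe_closed(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidContourError(f"contour {self.label!r}: points must be (N, 2)")
        if len(pts) < 3:
            raise InvalidContourError(
                f"contour {self.label!r}: needs >=3 distinct points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError(f"contour {self.label!r}: non-finite coordinates")
        if self.frame not in _FRAMES:
            raise InvalidContourError(
                f"contour {self.label!r}: unknown frame {self.frame!r}"
            )
        a = signed_area(pts)
        if abs(a) < 1e-12:
            raise InvalidContourError(f"contour {self.label!r}: zero enclosed area")
        if a < 0:
            pts = pts[::-1].copy()
        if not shapely.Polygon(pts).is_valid:
            raise InvalidContourError(f"contour {self.label!r}: self-intersecting boundary")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    # -- derived quantities -------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed area, mm^2 (positive; contours are stored CCW)."""
        return signed_area(self.points)

    @property
    def centroid(self) -> Tuple[float, float]:
        return area_centroid(self.points)

    @property
    def perimeter(self) -> float:
        seg = np.linalg.norm(np.roll(self.points, -1, axis=0) - self.points, axis=1)
        return float(seg.sum())

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.points)

    def with_points(self, points: np.ndarray, frame: str | None = None) -> "Contour2D":
        return Contour2D(self.label, points, self.frame if frame is None else frame)


def polygon_area(c: Union[Contour2D, np.ndarray, Sequence[Point2]]) -> float:
    """Signed area (mm^2) of a contour or raw vertex array.

    Positive for counter-clockwise input; ``Contour2D`` instances are stored
    CCW so their area is always positive.  Reversing the vertex order negates
    the result; the magnitude does not depend on the starting vertex.
    """
    pts = c.points if isinstance(c, Contour2D) else c
    return signed_area(pts)


def polygon_centroid(c: Union[Contour2D, np.ndarray, Sequence[Point2]]) -> Tuple[float, float]:
    """Area-weighted centroid (mm) of the enclosed region."""
    pts = c.points if isinstance(c, Contour2D) else c
    return area_centroid(pts)


# ---------------------------------------------------------------------------
# Rigid pose
# ---------------------------------------------------------------------------

def _norm_angle_deg(theta: float) -> float:
    """Normalize an angle to the interval (-180, 180]."""
    t = math.fmod(float(theta), 360.0)
    if t <= -180.0:
        t += 360.0
    elif t > 180.0:
        t -= 360.0
    return t


@dataclasses.dataclass(frozen=True)
class RigidPose2:
    """Rigid placement of an image frame in the base frame.

    ``theta_deg`` rotates counter-clockwise about the image-frame origin;
    ``anchor`` is where that origin (the image's characteristic corner) lands
    in the base frame.  A point ``p`` maps as ``R(theta) @ p + anchor``.
    """

    theta_deg: float
    anchor: Point2 = (0.0, 0.0)

    def __post_init__(self):
        t = _norm_angle_deg(self.theta_deg)
        a = (float(self.anchor[0]), float(self.anchor[1]))
        if not (math.isfinite(t) and math.isfinite(a[0]) and math.isfinite(a[1])):
            raise GeometryError("non-finite pose parameters")
        object.__setattr__(self, "theta_deg", t)
        object.__setattr__(self, "anchor", a)

    @classmethod
    def identity(cls) -> "RigidPose2":
        return cls(0.0, (0.0, 0.0))

    @property
    def is_identity(self) -> bool:
        return self.theta_deg == 0.0 and self.anchor == (0.0, 0.0)

    def rotation(self) -> np.ndarray:
        t = math.radians(self.theta_deg)
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation().T + np.asarray(self.anchor)

    def inverse(self) -> "RigidPose2":
        rinv = self.rotation().T
        t = -rinv @ np.asarray(self.anchor)
        return RigidPose2(-self.theta_deg, (float(t[0]), float(t[1])))


def transform_contour(c: Contour2D, pose: RigidPose2, frame: str = FRAME_BASE) -> Contour2D:
    """Rigidly place an image-frame contour in the base frame.

    Each vertex is rotated by ``pose.theta_deg`` about the image-frame origin
    and translated so the origin maps to ``pose.anchor``.  Area is preserved.
    """
    return c.with_points(pose.apply(c.points), frame=frame)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def arc_positions(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Cumulative arc length at each vertex of the closed loop, and perimeter."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum, float(cum[-1])


def resample_contour(c: Contour2D, n: int, preserve_vertices: bool = False) -> Contour2D:
    """Resample a contour to ``n`` points equally spaced by arc length.

    The first output point coincides with the input's first vertex.  With
    ``preserve_vertices`` (used by the lofter) and ``n >= 2 * n_input``, the
    arc-length sample nearest each original vertex is snapped onto it so
    polygon corners survive resampling.
    """
    if n < 3:
        raise InvalidContourError(f"resample needs n >= 3, got {n}")
    pts = c.points
    cum, per = arc_positions(pts)
    s = np.arange(n) * per / n
    if preserve_vertices and n >= 2 * len(pts):
        s = s.copy()
        step = per / n
        used = set()
        for sv in cum[:-1]:
            i = int(round(sv / step)) % n
            if i not in used:
                s[i] = sv
                used.add(i)
        s = np.sort(s)
    closed = np.vstack([pts, pts[:1]])
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return c.with_points(np.column_stack([x, y]))
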
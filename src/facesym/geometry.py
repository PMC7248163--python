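"""Minimal 3D geometry: distances, plane construction, point-to-plane distances.

The reference plane through nasion, sella and MidZ is the only plane used in
the analysis.  Its orientation is fixed by an explicit left-side witness
landmark rather than any axis convention, which keeps the whole method free
of a global coordinate frame: "left" is wherever the labelled left Z point
(or, as a fallback, left porion) lies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .landmarks import Point3

__all__ = ["ReferencePlane", "distance", "plane_from_points", "signed_plane_distance"]

#: Triangle area below this (mm^2) means the plane points are collinear.
#: Landmark coordinates are on a 10-100 mm scale, so this is far below
#: placement noise.
COLLINEARITY_AREA_TOL = 1e-6

#: A witness closer to the plane than this (mm) cannot fix orientation.
WITNESS_TOL = 1e-9


@dataclass(frozen=True)
class ReferencePlane:
    """An oriented plane ``dot(normal, p) + offset = 0`` with unit normal.

    The normal points toward the labelled left side: the witness landmark
    used at construction has non-negative signed distance.
    """

    normal: tuple[float, float, float]
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(float(np.linalg.norm(n)) - 1.0) > 1e-9:
            raise GeometryError("plane normal must be a unit vector")


def _vec(p: Point3) -> np.ndarray:
    return np.array(p.as_tuple(), dtype=float)


def distance(a: Point3, b: Point3) -> float:
    """Euclidean distance in mm between two points."""
    return float(np.linalg.norm(_vec(a) - _vec(b)))


def plane_from_points(
    p1: Point3,
    p2: Point3,
    p3: Point3,
    left_witness: Point3,
    fallback_witness: Point3 | None = None,
) -> ReferencePlane:
    """Oriented plane through three points, normal toward the left witness.

    The witness (normally Z(L)) must lie off the plane; if it is coplanar the
    fallback witness (Po(L)) is tried.  Collinear defining points or
    all-coplanar witnesses raise :class:`GeometryError`.
    """
    a, b, c = _vec(p1), _vec(p2), _vec(p3)
    cross = np.cross(b - a, c - a)
    area = float(np.linalg.norm(cross)) / 2.0
    if area < COLLINEARITY_AREA_TOL:
        raise GeometryError(
            f"reference landmarks are collinear (triangle area {area:.3g} mm^2)"
        )
    normal = cross / np.linalg.norm(cross)
    offset = -float(np.dot(normal, a))

    for witness in (left_witness, fallback_witness):
        if witness is None:
            continue
        d = float(np.dot(normal, _vec(witness))) + offset
        if abs(d) > WITNESS_TOL:
            if d < 0:
                normal = -normal
                offset = -offset
            return ReferencePlane(normal=tuple(normal.tolist()), offset=offset)
    raise GeometryError("cannot orient reference plane: all witnesses are coplanar with it")


def signed_plane_distance(plane: ReferencePlane, p: Point3) -> float:
    """Signed perpendicular distance in mm; positive on the left-witness side."""
    return float(np.dot(np.asarray(plane.normal), _vec(p))) + plane.offset
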
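"""2D geometric primitives for landmark-based measurements.

Coordinate convention
---------------------
All points are (x, y) in millimetres with x increasing anteriorly and y
increasing superiorly (subject facing +x).  Signed angles are
counterclockwise-positive in this frame; for a subject facing right this
means "opening upward" rotations are positive.

Sign convention for point-to-line distances: the positive side of a
directed line a -> b is the side reached by rotating the line direction
90 degrees counterclockwise.  Measurement definitions pick the point
order of each reference line so that their documented clinical sign
(usually anterior-positive) holds.
"""

from __future__ import annotations

import numpy as np

#: Two points closer than this (mm) are treated as coincident.
COINCIDENCE_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a primitive receives geometrically degenerate input."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2D point, got shape {a.shape}")
    return a


def direction(a, b) -> np.ndarray:
    """Unit direction vector of the directed segment a -> b."""
    a, b = _as_point(a), _as_point(b)
    v = b - a
    n = float(np.hypot(v[0], v[1]))
    if n < COINCIDENCE_TOL:
        raise DegenerateGeometryError(
            f"coincident points {tuple(a)} and {tuple(b)} define no direction"
        )
    return v / n


def vector_angle(u_from, u_to, v_from, v_to, signed: bool = False) -> float:
    """Angle in degrees between directed segments u_from->u_to and v_from->v_to.

    Unsigned result lies in [0, 180]; signed result is the
    counterclockwise rotation taking u onto v, in (-180, 180].
    """
    u = direction(u_from, u_to)
    v = direction(v_from, v_to)
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    ang = float(np.degrees(np.arctan2(cross, dot)))
    if signed:
        return 180.0 if ang == -180.0 else ang
    return abs(ang)


def three_point_angle(p, vertex, q) -> float:
    """Interior angle at *vertex* between rays vertex->p and vertex->q, in [0, 180]."""
    return vector_angle(vertex, p, vertex, q, signed=False)


def line_angle(l1_a, l1_b, l2_a, l2_b, signed: bool = False) -> float:
    """Angle between the (undirected) lines through the given point pairs.

    Unsigned result is in [0, 90]; signed result is in (-90, 90], the
    counterclockwise rotation taking line 1 onto line 2 modulo 180.
    """
    ang = vector_angle(l1_a, l1_b, l2_a, l2_b, signed=True)
    # collapse the directed angle to the undirected line angle
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    if signed:
        return 90.0 if ang == -90.0 else ang
    return abs(ang)


def signed_point_line_distance(p, line_a, line_b) -> float:
    """Perpendicular distance (mm) from p to the line through line_a -> line_b.

    Positive on the counterclockwise side of the directed line.
    """
    p = _as_point(p)
    a = _as_point(line_a)
    u = direction(line_a, line_b)
    w = p - a
    return float(u[0] * w[1] - u[1] * w[0])


def projection_coordinate(p, line_a, line_b) -> float:
    """Scalar coordinate (mm) of p projected onto the directed line a -> b.

    The origin of the coordinate is line_a; positive along the a -> b
    direction.
    """
    p = _as_point(p)
    a = _as_point(line_a)
    u = direction(line_a, line_b)
    w = p - a
    return float(u[0] * w[0] + u[1] * w[1])


def point_distance(p, q) -> float:
    """Euclidean distance between two points (mm)."""
    p, q = _as_point(p), _as_point(q)
    return float(np.hypot(*(q - p)))


def midpoint(p, q) -> np.ndarray:
    return (_as_point(p) + _as_point(q)) / 2.0


def perpendicular_through(point, line_a, line_b) -> tuple[np.ndarray, np.ndarray]:
    """Return two points spanning the line through *point* perpendicular to a -> b.

    The returned directed pair follows the counterclockwise rotation of
    the a -> b direction, so the positive side of the perpendicular line
    (per :func:`signed_point_line_distance`) is 90 degrees further ccw.
    """
    p = _as_point(point)
    u = direction(line_a, line_b)
    perp = np.array([-u[1], u[0]])
    return p, p + perp
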
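"""Independent brute-force recomputation of every quantity under test.

Deliberately written in pure ``math`` (no numpy, no imports from the
package) so that a bug in the library cannot hide in the oracle.  Points are
plain (x, y, z) tuples; sets are dicts ``(name, side) -> tuple``.
"""

import math


def dist(a, b):
    return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))


def midpoint(a, b):
    return tuple((u + v) / 2.0 for u, v in zip(a, b))


def _sub(a, b):
    return tuple(u - v for u, v in zip(a, b))


def _cross(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _dot(a, b):
    return sum(u * v for u, v in zip(a, b))


def perp_distance_to_plane(p, q1, q2, q3):
    """Unsigned distance from p to the plane through q1, q2, q3."""
    n = _cross(_sub(q2, q1), _sub(q3, q1))
    norm = math.sqrt(_dot(n, n))
    return abs(_dot(n, _sub(p, q1))) / norm


def bilateral_oracle(points, landmark, tie_tol=1e-6):
    """(magnitude, direction) for a bilateral landmark, from raw distances."""
    s, n = points[("S", "M")], points[("N", "M")]
    midz = midpoint(points[("Z", "L")], points[("Z", "R")])
    p_l, p_r = points[(landmark, "L")], points[(landmark, "R")]
    diffs = [dist(r, p_l) - dist(r, p_r) for r in (s, n, midz)]
    magnitude = math.sqrt(sum(d * d for d in diffs))
    perp_l = perp_distance_to_plane(p_l, n, s, midz)
    perp_r = perp_distance_to_plane(p_r, n, s, midz)
    if perp_l - perp_r > tie_tol:
        direction = "left"
    elif perp_r - perp_l > tie_tol:
        direction = "right"
    else:
        direction = "none"
    return magnitude, direction


def midsagittal_oracle(points, landmark, tie_tol=1e-6):
    """(magnitude, direction) for a midline landmark, from raw distances."""
    m = points[(landmark, "M")]
    dl_z = dist(points[("Z", "L")], m)
    dr_z = dist(points[("Z", "R")], m)
    dl_po = dist(points[("Po", "L")], m)
    dr_po = dist(points[("Po", "R")], m)
    magnitude = math.sqrt((dl_z - dr_z) ** 2 + (dl_po - dr_po) ** 2)
    s = (dr_z - dl_z) + (dr_po - dl_po)
    if s > tie_tol:
        direction = "left"
    elif s < -tie_tol:
        direction = "right"
    else:
        direction = "none"
    return magnitude, direction


def dahlberg_oracle(diffs):
    return math.sqrt(sum(d * d for d in diffs) / (2.0 * len(diffs)))
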
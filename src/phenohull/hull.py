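"""Fast 2D convex hull (quickhull) with silhouette-chain decomposition.

The hull of each projected silhouette is built by the divide-and-conquer
quickhull scheme: the extreme points of the lateral coordinate seed a
baseline that splits the set into two half-planes; each recursion keeps
only the points strictly outside the current edge and splits at the point
farthest from it.  No global angular sort is needed, which is what makes
the method fast on dense silhouettes.

A hull is then cut at its topmost and bottommost vertices into a *left
chain* and a *right chain* (top -> bottom), mirroring how a human reads a
plant outline, and each chain may be simplified with a Douglas-Peucker
pass so that sampling micro-corners do not masquerade as architectural
corners.

Points throughout are ``(u, v)`` pairs with ``u`` the vertical coordinate
and ``v`` the lateral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hull2D",
    "side_of_line",
    "point_line_distance",
    "quickhull",
    "split_chains",
    "simplify_chain",
    "DEFAULT_SIMPLIFY_TOL",
]

#: Default Douglas-Peucker tolerance, in normalized units — 1% of the
#: standard normalized plant height of 5.
DEFAULT_SIMPLIFY_TOL = 0.05

# Strict-outside tolerance for the half-plane test, relative to the squared
# coordinate magnitude (the test statistic is a 2x2 determinant).
_REL_TOL = 1e-12


@dataclass(frozen=True)
class Hull2D:
    """Convex polygon with its silhouette-chain decomposition.

    ``vertices`` are in counter-clockwise order with no repeats;
    ``left_chain`` and ``right_chain`` run top -> bottom and partition the
    vertex cycle (sharing the extreme vertices when those are unique).
    """

    vertices: np.ndarray
    left_chain: np.ndarray = field(default=None)  # type: ignore[assignment]
    right_chain: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "vertices", verts)
        if self.left_chain is None or self.right_chain is None:
            left, right = split_chains(verts)
            object.__setattr__(self, "left_chain", left)
            object.__setattr__(self, "right_chain", right)


def side_of_line(a, b, p) -> float:
    """Signed position statistic F of point ``p`` relative to line ``ab``.

    ``F = X_A(Y_B - Y_P) - Y_A(X_B - X_P) + (X_B Y_P - X_P Y_B)``, which is
    the cross product ``(b - a) x (p - a)``: zero iff ``p`` is on the line,
    positive on one side, negative on the other.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.array_equal(a, b):
        raise ValueError("line endpoints coincide")
    return float(
        a[0] * (b[1] - p[1]) - a[1] * (b[0] - p[0])
        + (b[0] * p[1] - p[0] * b[1])
    )


def point_line_distance(a, b, p) -> float:
    """Perpendicular distance from ``p`` to the line through ``a`` and
    ``b``: ``|ax + by + c| / sqrt(a^2 + b^2)`` with the line written as
    ``ax + by + c = 0`` (coefficients from the two endpoints)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.array_equal(a, b):
        raise ValueError("line endpoints coincide")
    ca = b[1] - a[1]
    cb = a[0] - b[0]
    cc = b[0] * a[1] - a[0] * b[1]
    return float(abs(ca * p[0] + cb * p[1] + cc) / np.hypot(ca, cb))


def _cross(a, b, pts):
    """Vectorized signed side statistic for many points at once."""
    return (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (
        pts[:, 0] - a[0]
    )


def _expand(a: np.ndarray, b: np.ndarray, pts: np.ndarray, tol: float):
    """Hull vertices strictly right of the directed edge a->b, in boundary
    order from a to b (exclusive)."""
    if len(pts) == 0:
        return []
    # farthest point from line ab; |cross| is proportional to distance
    dev = -_cross(a, b, pts)  # positive for points right of a->b
    far = int(np.argmax(dev))
    c = pts[far]
    right_ac = pts[-_cross(a, c, pts) > tol]
    right_cb = pts[-_cross(c, b, pts) > tol]
    return _expand(a, c, right_ac, tol) + [c] + _expand(c, b, right_cb, tol)


def quickhull(points) -> Hull2D:
    """Minimal convex polygon of a 2D point set by divide and conquer.

    The extreme-lateral points seed the baseline; recursion keeps only
    points strictly outside each edge (beyond a relative tolerance) and
    splits at the farthest point.  Output vertices are a subset of the
    input in counter-clockwise order; collinear boundary points are not
    vertices.

    Raises on fewer than 3 points or an all-collinear set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a 2D hull")
    tol = _REL_TOL * max(1.0, float(np.abs(pts).max())) ** 2

    # baseline: extreme lateral coordinates, ties broken by vertical
    v = pts[:, 1]
    u = pts[:, 0]
    left_mask = v == v.min()
    ia = int(np.flatnonzero(left_mask)[np.argmax(u[left_mask])])
    right_mask = v == v.max()
    ib = int(np.flatnonzero(right_mask)[np.argmin(u[right_mask])])
    a, b = pts[ia], pts[ib]
    if np.array_equal(a, b):
        raise ValueError("all points coincide")

    side = _cross(a, b, pts)
    lower = pts[-side > tol]  # right of a->b
    upper = pts[side > tol]   # right of b->a
    if len(lower) == 0 and len(upper) == 0:
        raise ValueError("all points are collinear")

    verts = (
        [a] + _expand(a, b, lower, tol) + [b] + _expand(b, a, upper, tol)
    )
    return Hull2D(vertices=np.array(verts))


def _extreme_indices(u: np.ndarray, value: float, tol: float) -> np.ndarray:
    return np.flatnonzero(np.abs(u - value) <= tol)


def split_chains(vertices) -> tuple[np.ndarray, np.ndarray]:
    """Cut a convex vertex cycle into left and right chains, top -> bottom.

    The cycle is cut at the vertices of maximum and minimum vertical
    coordinate.  A unique extreme vertex belongs to both chains; when
    several vertices tie for an extreme, the tied vertices become the
    chain terminals and the connecting cap edge belongs to neither chain.
    """
    verts = np.asarray(vertices, dtype=float).reshape(-1, 2)
    n = len(verts)
    if n < 3:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    u = verts[:, 0]
    v = verts[:, 1]
    tol = 1e-9 * max(1.0, float(np.abs(u).max()))
    tops = _extreme_indices(u, u.max(), tol)
    bots = _extreme_indices(u, u.min(), tol)

    # chain terminals: on ties, split the tied cap by lateral coordinate
    t_left = int(tops[np.argmin(v[tops])])
    t_right = int(tops[np.argmax(v[tops])])
    b_left = int(bots[np.argmin(v[bots])])
    b_right = int(bots[np.argmax(v[bots])])

    # CCW walk from the top-right terminal descends the right chain to the
    # bottom-right terminal; continuing from bottom-left ascends the left.
    right_chain = [verts[t_right]]
    i = t_right
    while i != b_right:
        i = (i + 1) % n
        right_chain.append(verts[i])
    left_rev = [verts[b_left]]
    i = b_left
    while i != t_left:
        i = (i + 1) % n
        left_rev.append(verts[i])
    left_chain = left_rev[::-1]
    return np.array(left_chain), np.array(right_chain)


def simplify_chain(chain, tol: float = DEFAULT_SIMPLIFY_TOL) -> np.ndarray:
    """Douglas-Peucker reduction of an ordered polyline, keeping endpoints.

    Every removed vertex lies within perpendicular distance ``tol`` of the
    simplified polyline; ``tol = 0`` is the identity.
    """
    pts = np.asarray(chain, dtype=float).reshape(-1, 2)
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if len(pts) <= 2 or tol == 0:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    _dp(pts, 0, len(pts) - 1, tol, keep)
    return pts[keep]


def _dp(pts, lo, hi, tol, keep):
    if hi - lo < 2:
        return
    a, b = pts[lo], pts[hi]
    if np.array_equal(a, b):
        # closed loop segment: fall back to distance from the point itself
        dev = np.hypot(pts[lo + 1:hi, 0] - a[0], pts[lo + 1:hi, 1] - a[1])
    else:
        ca = b[1] - a[1]
        cb = a[0] - b[0]
        cc = b[0] * a[1] - a[0] * b[1]
        dev = np.abs(
            ca * pts[lo + 1:hi, 0] + cb * pts[lo + 1:hi, 1] + cc
        ) / np.hypot(ca, cb)
    far = int(np.argmax(dev)) + lo + 1
    if dev[far - lo - 1] > tol:
        keep[far] = True
        _dp(pts, lo, far, tol, keep)
        _dp(pts, far, hi, tol, keep)
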
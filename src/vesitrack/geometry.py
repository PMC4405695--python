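"""Minimal enclosing circle of a 2-D point set.

Randomised incremental (Welzl-style move-to-front) construction,
expected linear time in the number of points.  The circle is used to
summarise the area explored by a confined particle trajectory, so
exactness matters more than speed: the implementation is checked in the
test suite against brute-force enumeration of all pair and triple
circles.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

# Relative slack used in containment tests so that points lying exactly
# on a circle built through them are reported inside despite rounding.
_EPS = 1e-12


class Circle(NamedTuple):
    cx: float
    cy: float
    r: float

    @property
    def area(self) -> float:
        return math.pi * self.r * self.r

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x - self.cx, y - self.cy) <= self.r * (1 + _EPS) + _EPS


def _circle_from_two(ax, ay, bx, by) -> Circle:
    cx = (ax + bx) / 2.0
    cy = (ay + by) / 2.0
    return Circle(cx, cy, math.hypot(ax - cx, ay - cy))


def _circumcircle(ax, ay, bx, by, cx, cy) -> Circle | None:
    """Circle through three points; None if (near-)collinear."""
    # shift to improve conditioning
    ox = (ax + bx + cx) / 3.0
    oy = (ay + by + cy) / 3.0
    ax, ay = ax - ox, ay - oy
    bx, by = bx - ox, by - oy
    cx, cy = cx - ox, cy - oy
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy)
          + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx)
          + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return Circle(ux + ox, uy + oy, math.hypot(ux - ax, uy - ay))


def _cross(ax, ay, bx, by, px, py) -> float:
    return (bx - ax) * (py - ay) - (by - ay) * (px - ax)


def _with_two_on_boundary(pts, p, q) -> Circle:
    circ = _circle_from_two(p[0], p[1], q[0], q[1])
    left: Circle | None = None
    right: Circle | None = None
    for rx, ry in pts:
        if circ.contains(rx, ry):
            continue
        side = _cross(p[0], p[1], q[0], q[1], rx, ry)
        c = _circumcircle(p[0], p[1], q[0], q[1], rx, ry)
        if c is None:
            continue
        cside = _cross(p[0], p[1], q[0], q[1], c.cx, c.cy)
        if side > 0 and (left is None
                         or cside > _cross(p[0], p[1], q[0], q[1], left.cx, left.cy)):
            left = c
        elif side < 0 and (right is None
                           or cside < _cross(p[0], p[1], q[0], q[1], right.cx, right.cy)):
            right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right  # type: ignore[return-value]
    if right is None:
        return left
    return left if left.r <= right.r else right


def _with_one_on_boundary(pts, p) -> Circle:
    c = Circle(float(p[0]), float(p[1]), 0.0)
    for j in range(len(pts)):
        qx, qy = pts[j]
        if c.contains(qx, qy):
            continue
        if c.r == 0.0:
            c = _circle_from_two(p[0], p[1], qx, qy)
        else:
            c = _with_two_on_boundary(pts[: j + 1], p, (qx, qy))
    return c


def minimal_enclosing_circle(points: np.ndarray, *, shuffle_seed: int = 0) -> Circle:
    """Smallest circle containing all ``points`` (array of shape (n, 2)).

    The point order is shuffled deterministically (``shuffle_seed``) so
    the expected-linear-time bound holds regardless of input order; the
    resulting circle is order-independent up to floating-point rounding.

    Degenerate inputs: one point gives a zero-radius circle, two points
    (or any collinear set) give the diameter circle of the extremes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) == 0:
        raise ValueError("points must be non-empty")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return Circle(pts[0, 0], pts[0, 1], 0.0)
    order = np.random.default_rng(shuffle_seed).permutation(len(pts))
    pts = [tuple(pts[i]) for i in order]
    c: Circle | None = None
    for i, p in enumerate(pts):
        if c is None or not c.contains(p[0], p[1]):
            c = _with_one_on_boundary(pts[:i], p)
    assert c is not None
    return c
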
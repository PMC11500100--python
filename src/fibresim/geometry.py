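"""Exact 2D geometry for line-segment (rod) agents.

Matrix fibres are modelled as thin cylinders whose girth is much smaller than
their length (collagen: ~75 um long, ~2 um radius), so in 2D they are handled
as closed line segments carrying a nominal radius.  This module provides the
three geometric primitives everything else is built on:

* the nearest point on a fibre axis to an arbitrary point (cell centre),
* the closest approach between two fibre axes, used to decide whether two
  fibres touch/intersect and therefore cross-link,
* the exact set of grid voxels a fibre axis passes through, used for
  neighbour registration.

All functions are pure and operate on :class:`Segment` values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "nearest_point_on_fibre",
    "segment_segment_closest",
    "check_fibre_crosslinks",
    "voxels_crossed",
]

_UNIT_TOL = 1e-9


@dataclass
class Segment:
    """A closed line segment with a nominal (cylinder) radius.

    Parameters
    ----------
    centre : (2,) array-like, um
        Midpoint of the segment.
    orientation : (2,) array-like
        Unit vector along the axis (|orientation| = 1 within 1e-9).
    length : float, um
        Total axis length (> 0); endpoints are centre +/- length/2 * orientation.
    radius : float, um
        Cylinder radius (> 0).  Ignored for voxel registration but used for
        contact and cross-link tests.
    """

    centre: np.ndarray
    orientation: np.ndarray
    length: float
    radius: float

    def __post_init__(self) -> None:
        self.centre = np.array(self.centre, dtype=float)
        self.orientation = np.array(self.orientation, dtype=float)
        if self.centre.shape != (2,) or self.orientation.shape != (2,):
            raise ValueError("centre and orientation must be 2-vectors")
        norm = float(np.hypot(self.orientation[0], self.orientation[1]))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"orientation must be a unit vector (|o| = {norm})")
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    @classmethod
    def from_angle(cls, centre, angle: float, length: float, radius: float) -> "Segment":
        return cls(np.asarray(centre, dtype=float),
                   np.array([np.cos(angle), np.sin(angle)]),
                   float(length), float(radius))

    @property
    def start(self) -> np.ndarray:
        return self.centre - 0.5 * self.length * self.orientation

    @property
    def end(self) -> np.ndarray:
        return self.centre + 0.5 * self.length * self.orientation

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.orientation[1], self.orientation[0]))

    def point_at(self, t: float) -> np.ndarray:
        """Point at normalised axis parameter t in [0, 1] (0 = start, 1 = end)."""
        return self.start + t * self.length * self.orientation


def nearest_point_on_fibre(point, seg: Segment) -> np.ndarray:
    """Nearest point on the closed axis segment of ``seg`` to ``point``.

    Operates on the axis, not the inflated cylinder; the displacement vector
    from the fibre to the point is ``point - nearest_point_on_fibre(point, seg)``.
    Total function: clamps to the nearer endpoint outside the span.
    """
    p = np.asarray(point, dtype=float)
    half = 0.5 * seg.length
    t = float(np.dot(p - seg.centre, seg.orientation))
    t = min(max(t, -half), half)
    return seg.centre + t * seg.orientation


def segment_segment_closest(a: Segment, b: Segment) -> tuple[float, np.ndarray, np.ndarray]:
    """Closest approach between the two closed axis segments.

    Returns ``(distance, point_on_a, point_on_b)`` using the clamped
    parametric closed form (no sampling).
    """
    p1, d1 = a.start, a.end - a.start
    p2, d2 = b.start, b.end - b.start
    r = p1 - p2
    aa = float(np.dot(d1, d1))
    bb = float(np.dot(d1, d2))
    cc = float(np.dot(d2, d2))
    dd = float(np.dot(d1, r))
    ee = float(np.dot(d2, r))
    denom = aa * cc - bb * bb
    # minimise |s*d1 - t*d2 + r|^2 over the unit square
    if denom > 1e-14 * aa * cc:
        s = (bb * ee - cc * dd) / denom
        s = min(max(s, 0.0), 1.0)
    else:  # nearly parallel axes
        s = 0.0
    t = (ee + bb * s) / cc
    if t < 0.0:
        t = 0.0
        s = min(max(-dd / aa, 0.0), 1.0)
    elif t > 1.0:
        t = 1.0
        s = min(max((bb - dd) / aa, 0.0), 1.0)
    pa = p1 + s * d1
    pb = p2 + t * d2
    return float(np.hypot(*(pa - pb))), pa, pb


def check_fibre_crosslinks(a: Segment, b: Segment) -> np.ndarray | None:
    """Contact point where two fibres touch or intersect, else ``None``.

    Two fibres of finite girth cross-link wherever the minimum distance
    between their axes is at most the sum of their radii; the contact point is
    the midpoint of the closest-approach pair (the intersection point when the
    axes properly cross).  Symmetric in its arguments.
    """
    dist, pa, pb = segment_segment_closest(a, b)
    if dist <= a.radius + b.radius:
        return 0.5 * (pa + pb)
    return None


def _axis_interval(p0: float, d: float, lo: float, hi: float,
                   t0: float, t1: float, eps: float) -> tuple[float, float]:
    """Clip parameter interval [t0, t1] against slab lo <= p0 + t*d <= hi."""
    if abs(d) < eps:
        if lo - eps <= p0 <= hi + eps:
            return t0, t1
        return 1.0, 0.0  # empty
    ta = (lo - p0) / d
    tb = (hi - p0) / d
    if ta > tb:
        ta, tb = tb, ta
    return max(t0, ta), min(t1, tb)


def voxels_crossed(seg: Segment, grid_spec) -> set[tuple[int, int]]:
    """Every voxel whose closed square intersects the axis of ``seg``.

    ``grid_spec`` is any object with ``x_min, x_max, y_min, y_max,
    voxel_size, nx, ny`` attributes (see ``initialization.Domain``).  The
    fibre radius is ignored: registration uses the axis only.  Ownership is
    inclusive: an axis running along a voxel boundary registers to the voxels
    on both sides (over-registration is safe for neighbour finding;
    under-registration would drop interactions).

    Raises ``ValueError`` if either endpoint lies outside the grid.
    """
    g = grid_spec
    h = g.voxel_size
    eps = 1e-9 * max(h, 1.0)
    p0, p1 = seg.start, seg.end
    for p in (p0, p1):
        if not (g.x_min - eps <= p[0] <= g.x_max + eps
                and g.y_min - eps <= p[1] <= g.y_max + eps):
            raise ValueError(f"segment endpoint {p} outside the grid")
    d = p1 - p0
    i_lo = max(0, int(np.floor((min(p0[0], p1[0]) - g.x_min) / h)) - 1)
    i_hi = min(g.nx - 1, int(np.floor((max(p0[0], p1[0]) - g.x_min) / h)) + 1)
    j_lo = max(0, int(np.floor((min(p0[1], p1[1]) - g.y_min) / h)) - 1)
    j_hi = min(g.ny - 1, int(np.floor((max(p0[1], p1[1]) - g.y_min) / h)) + 1)
    out: set[tuple[int, int]] = set()
    for i in range(i_lo, i_hi + 1):
        x0 = g.x_min + i * h
        ta, tb = _axis_interval(p0[0], d[0], x0 - eps, x0 + h + eps, 0.0, 1.0, eps)
        if ta > tb:
            continue
        for j in range(j_lo, j_hi + 1):
            y0 = g.y_min + j * h
            sa, sb = _axis_interval(p0[1], d[1], y0 - eps, y0 + h + eps, ta, tb, eps)
            if sa <= sb:
                out.add((i, j))
    return out
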
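"""Spherocylinder geometry primitives.

A spherocylinder (capsule) is a cylinder of length ``length`` and diameter
``diameter`` capped by two hemispheres; ``length`` is the cylinder-segment
length only, so a cell's tip-to-tip extent is ``length + diameter`` and
``length == 0`` describes a sphere.  It is the standard geometric model for
rod-shaped bacteria such as *E. coli*.

All physical 3-vectors in this package are ordered ``(z, y, x)`` in µm so
that they line up with numpy array indexing; serialization to tables uses
x/y/z column order (see :mod:`biofilm3d.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spherocylinder",
    "point_segment_distance",
    "segment_segment_distance",
    "orthonormal_frame",
    "random_unit_vector",
]


def _as_unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis must be a nonzero vector")
    if abs(n - 1.0) < 1e-12:
        return v  # already unit: keep bit-exact (serialization round trips)
    return v / n


@dataclass(frozen=True)
class Spherocylinder:
    """A single rod-shaped (or spherical) cell.

    Parameters
    ----------
    cell_id : positive integer, unique within an arrangement.
    centroid : (z, y, x) position of the cell center, µm.
    axis : unit orientation vector (sign-ambiguous), (z, y, x).
    length : cylinder-segment length in µm; 0 for a sphere.
    diameter : cell diameter in µm.
    population : small integer population label (1 or 2).
    """

    cell_id: int
    centroid: np.ndarray
    axis: np.ndarray
    length: float
    diameter: float
    population: int = 1

    def __post_init__(self):
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "axis", _as_unit(self.axis))
        if self.cell_id <= 0:
            raise ValueError("cell_id must be positive")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.length < 0:
            raise ValueError("length must be non-negative")

    # -- derived quantities -------------------------------------------------

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def total_length(self) -> float:
        """Tip-to-tip extent, µm."""
        return self.length + self.diameter

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the central axis segment."""
        h = 0.5 * self.length * self.axis
        return self.centroid - h, self.centroid + h

    @property
    def volume(self) -> float:
        r = self.radius
        return np.pi * r * r * self.length + (4.0 / 3.0) * np.pi * r**3

    @property
    def surface_area(self) -> float:
        r = self.radius
        return 2.0 * np.pi * r * self.length + 4.0 * np.pi * r * r

    # -- queries ------------------------------------------------------------

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point (n, 3) to the central axis segment."""
        p0, p1 = self.endpoints
        return point_segment_distance(np.atleast_2d(points), p0, p1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-test for points of shape (n, 3)."""
        return self.axis_distance(points) <= self.radius

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the surface (negative inside)."""
        return self.axis_distance(points) - self.radius

    # -- random sampling ----------------------------------------------------

    def sample_interior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points inside the cell volume, shape (n, 3)."""
        r = self.radius
        v_cyl = np.pi * r * r * self.length
        v_cap = (4.0 / 3.0) * np.pi * r**3
        in_cyl = rng.random(n) < v_cyl / (v_cyl + v_cap)
        e1, e2 = orthonormal_frame(self.axis)
        pts = np.empty((n, 3))

        n_cyl = int(in_cyl.sum())
        if n_cyl:
            t = rng.uniform(-0.5 * self.length, 0.5 * self.length, n_cyl)
            rad = r * np.sqrt(rng.random(n_cyl))
            ang = rng.uniform(0, 2 * np.pi, n_cyl)
            pts[in_cyl] = (
                self.centroid
                + t[:, None] * self.axis
                + (rad * np.cos(ang))[:, None] * e1
                + (rad * np.sin(ang))[:, None] * e2
            )
        n_cap = n - n_cyl
        if n_cap:
            # uniform in the unit ball, scaled; offset into the matching cap
            u = rng.normal(size=(n_cap, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            rad = r * rng.random(n_cap) ** (1.0 / 3.0)
            # each hemisphere of the ball maps to its matching end cap,
            # which is exactly uniform over the two caps
            ball = rad[:, None] * u
            side = np.sign(ball @ self.axis)
            side[side == 0] = 1.0
            centers = self.centroid + (side * 0.5 * self.length)[:, None] * self.axis
            pts[~in_cyl] = centers + ball
        return pts

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points on the cell surface, shape (n, 3)."""
        r = self.radius
        a_cyl = 2.0 * np.pi * r * self.length
        a_cap = 4.0 * np.pi * r * r
        on_cyl = rng.random(n) < a_cyl / (a_cyl + a_cap)
        e1, e2 = orthonormal_frame(self.axis)
        pts = np.empty((n, 3))

        n_cyl = int(on_cyl.sum())
        if n_cyl:
            t = rng.uniform(-0.5 * self.length, 0.5 * self.length, n_cyl)
            ang = rng.uniform(0, 2 * np.pi, n_cyl)
            pts[on_cyl] = (
                self.centroid
                + t[:, None] * self.axis
                + (r * np.cos(ang))[:, None] * e1
                + (r * np.sin(ang))[:, None] * e2
            )
        n_cap = n - n_cyl
        if n_cap:
            u = rng.normal(size=(n_cap, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            side = np.sign(u @ self.axis)
            side[side == 0] = 1.0
            centers = self.centroid + (side * 0.5 * self.length)[:, None] * self.axis
            pts[~on_cyl] = centers + r * u
        return pts

    def with_centroid(self, centroid: np.ndarray) -> "Spherocylinder":
        return replace(self, centroid=np.asarray(centroid, dtype=float))


def point_segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Euclidean distance from points (n, 3) to the segment [p0, p1]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0.0:
        return np.linalg.norm(points - p0, axis=-1)
    t = np.clip((points - p0) @ d / dd, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    return np.linalg.norm(points - closest, axis=-1)


def segment_segment_distance(
    p0: np.ndarray, p1: np.ndarray, q0: np.ndarray, q1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum distance between segment pairs, vectorized over leading axes.

    Parameters are arrays of shape (..., 3): segment one runs p0→p1, segment
    two q0→q1.  Returns ``(dist, cp, cq)`` where ``cp``/``cq`` are the closest
    points on each segment.  Implementation follows the standard clamped
    quadratic minimization (Ericson, Real-Time Collision Detection §5.1.9),
    vectorized with numpy.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)

    eps = 1e-14
    denom = a * e - b * b
    # general case
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    # degenerate: first segment is a point
    s = np.where(a <= eps, 0.0, s)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    # clamp t then recompute s
    t_cl = np.clip(t, 0.0, 1.0)
    need = (t_cl != t) & (a > eps)
    s_new = np.clip((t_cl * b - c) / np.where(a > eps, a, 1.0), 0.0, 1.0)
    s = np.where(need, s_new, s)
    t = t_cl

    cp = p0 + s[..., None] * d1
    cq = q0 + t[..., None] * d2
    dist = np.linalg.norm(cp - cq, axis=-1)
    return dist, cp, cq


def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to an orthonormal basis."""
    a = _as_unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def random_unit_vector(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Isotropic random unit vector(s)."""
    v = rng.normal(size=(size or 1, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if size is None else v
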
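"""Exact geometric primitives shared by the simulator and the reconstruction stack.

Conventions
-----------
All lengths are centimetres, all public angles degrees.  The room frame has
its origin at the nominal isocenter, ``Y`` along the nominal gantry rotation
axis, ``Z`` along the local vertical (up) and ``X = Y x Z``.  At gantry angle
0 the radiation source sits at ``(0, 0, SAD)`` and the beam points along
``-Z``; a gantry rotation by ``psi`` (degrees) moves the source to
``(SAD sin psi, 0, SAD cos psi)``.

Lines are unoriented: every operation on :class:`Line3` is invariant to
flipping the direction or sliding the anchor point along the line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .errors import DegenerateGeometryError

#: Absolute tolerance for geometric degeneracy checks (cm scale, double precision).
GEOM_EPS = 1e-9
#: Condition-number threshold above which a linear system is treated as rank deficient.
COND_MAX = 1e8

Vec3 = np.ndarray  # shape (3,), float


def vec3(x: float, y: float, z: float) -> Vec3:
    return np.array([x, y, z], dtype=float)


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize ``v``; raise if its norm is numerically zero."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalize a near-zero vector")
    return v / n


@dataclass(frozen=True)
class Line3:
    """Unoriented line: anchor point plus unit direction."""

    point: Vec3
    direction: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))


@dataclass(frozen=True)
class Plane3:
    """Plane through ``point`` with unit ``normal``."""

    point: Vec3
    normal: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        return np.asarray(p - self.point, dtype=float) @ self.normal


@dataclass(frozen=True)
class DetectorFrame:
    """A plane equipped with an orthonormal in-plane 2D coordinate frame.

    ``origin`` is the point with 2D coordinates (0, 0); ``e_u``/``e_v`` are the
    in-plane unit axes.  The plane normal is ``e_u x e_v`` (sign irrelevant to
    projections).
    """

    origin: Vec3
    e_u: Vec3
    e_v: Vec3

    def __post_init__(self) -> None:
        eu = unit(self.e_u)
        ev = unit(self.e_v)
        if abs(eu @ ev) > 1e-9:
            raise DegenerateGeometryError("detector in-plane axes must be orthogonal")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "e_u", eu)
        object.__setattr__(self, "e_v", ev)

    @property
    def normal(self) -> Vec3:
        return np.cross(self.e_u, self.e_v)

    @property
    def plane(self) -> Plane3:
        return Plane3(self.origin, self.normal)

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        """In-plane (u, v) coordinates of 3D ``points`` assumed on the plane."""
        d = np.atleast_2d(points) - self.origin
        uv = np.stack([d @ self.e_u, d @ self.e_v], axis=-1)
        return uv if np.asarray(points).ndim == 2 else uv[0]

    def to_3d(self, uv: np.ndarray) -> np.ndarray:
        single = np.asarray(uv).ndim == 1
        uv = np.atleast_2d(uv)
        pts = self.origin + np.outer(uv[:, 0], self.e_u) + np.outer(uv[:, 1], self.e_v)
        return pts[0] if single else pts


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def rotation_matrix(axis_direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about ``axis_direction`` (Rodrigues formula)."""
    a = unit(axis_direction)
    t = np.deg2rad(angle_deg)
    K = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


@dataclass(frozen=True)
class AxisRotation:
    """Rotation by ``angle_deg`` about an anchored axis; acts affinely on points."""

    axis: Line3
    angle_deg: float

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.axis.direction, self.angle_deg)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        a = self.axis.point
        return (p - a) @ self.matrix.T + a


def rotation_about_axis(axis: Line3, angle_deg: float) -> AxisRotation:
    return AxisRotation(axis, float(angle_deg))


def rotation_axis_of(R: np.ndarray, reference: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Rotation axis (unit) and angle (degrees) of a proper rotation matrix.

    The axis sign is chosen to have a non-negative dot product with
    ``reference`` (default: +Y hemisphere).  Near-identity rotations have no
    well-defined axis and raise.
    """
    rotvec = _ScipyRotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-6:
        raise DegenerateGeometryError("axis of a near-identity rotation is ill-defined")
    axis = rotvec / angle
    ref = np.array([0.0, 1.0, 0.0]) if reference is None else np.asarray(reference, dtype=float)
    if axis @ ref < 0:
        axis = -axis
    return axis, float(np.rad2deg(angle))


def optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Kabsch: proper rotation minimizing ``sum |Y_i - (R (X_i - Xbar) + Ybar)|^2``.

    Requires at least 3 corresponding points, non-collinear after centering.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (n, 3) arrays")
    if X.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 corresponding points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, s, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(Xc), 1e-30)
    if s[1] < 1e-9 * scale * scale:
        raise DegenerateGeometryError("point sets are collinear; rotation is ambiguous")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rigid_transform(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid motion ``x -> R x + t`` mapping X onto Y (Kabsch + centroids)."""
    R = optimal_rotation(X, Y)
    t = np.mean(Y, axis=0) - R @ np.mean(X, axis=0)
    return R, t


def fixed_line_of_rigid(R: np.ndarray, t: np.ndarray, reference: np.ndarray | None = None) -> Line3:
    """Fixed-point line of the rigid motion ``x -> R x + t``.

    Valid when the motion is (numerically) a pure rotation about some axis in
    space, i.e. ``t`` has no component along the rotation axis.  The anchor is
    the minimum-norm least-squares solution of ``(I - R) x = t``.
    """
    axis, _ = rotation_axis_of(R, reference)
    anchor, *_ = np.linalg.lstsq(np.eye(3) - R, np.asarray(t, dtype=float), rcond=1e-8)
    return Line3(anchor, axis)


def extrinsic_mean_directions(dirs: np.ndarray) -> np.ndarray:
    """Extrinsic (chordal) mean of unit vectors: the normalized arithmetic mean.

    Inputs must already lie in a common hemisphere; antipodal cancellation
    (mean norm < 1e-9) raises.
    """
    D = np.atleast_2d(np.asarray(dirs, dtype=float))
    if D.shape[0] < 1:
        raise DegenerateGeometryError("need at least one direction")
    m = D.mean(axis=0)
    if np.linalg.norm(m) < 1e-9:
        raise DegenerateGeometryError("directions cancel; extrinsic mean undefined")
    return m / np.linalg.norm(m)


# ---------------------------------------------------------------------------
# distances, intersections, projection
# ---------------------------------------------------------------------------


def point_line_distance(p: np.ndarray, line: Line3) -> float:
    d = np.asarray(p, dtype=float) - line.point
    return float(np.linalg.norm(d - (d @ line.direction) * line.direction))


def line_plane_intersection(line: Line3, plane: Plane3) -> Vec3:
    denom = line.direction @ plane.normal
    if abs(denom) < GEOM_EPS:
        raise DegenerateGeometryError("line is (near-)parallel to the plane")
    t = ((plane.point - line.point) @ plane.normal) / denom
    return line.point + t * line.direction


def central_projection(source: Vec3, detector: DetectorFrame, points: np.ndarray) -> np.ndarray:
    """Project ``points`` from ``source`` onto the detector; return (u, v) in cm.

    Rays parallel to the detector plane, or points coincident with the source,
    raise a degeneracy error.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = p - source
    if np.any(np.linalg.norm(d, axis=1) < GEOM_EPS):
        raise DegenerateGeometryError("point coincides with the source")
    n = detector.normal
    denom = d @ n
    if np.any(np.abs(denom) < GEOM_EPS):
        raise DegenerateGeometryError("projection ray is (near-)parallel to the detector")
    t = ((detector.origin - source) @ n) / denom
    if np.any(t <= 0):
        raise DegenerateGeometryError("point lies behind the source relative to the detector")
    hits = source + t[:, None] * d
    uv = detector.to_2d(hits)
    return uv if np.asarray(points).ndim == 2 else uv[0]


def closest_point_to_lines(lines: list[Line3]) -> Vec3:
    """Point minimizing the sum of squared distances to the given lines.

    Closed form via the normal equations of the summed orthogonal projectors
    ``sum_i (I - d_i d_i^T)``.  All-parallel line bundles leave the solution
    unconstrained along the common direction and raise.
    """
    if len(lines) < 2:
        raise DegenerateGeometryError("need at least two lines")
    M = np.zeros((3, 3))
    b = np.zeros(3)
    for ln in lines:
        P = np.eye(3) - np.outer(ln.direction, ln.direction)
        M += P
        b += P @ ln.point
    if np.linalg.cond(M) > COND_MAX:
        raise DegenerateGeometryError("lines are (near-)parallel; closest point ill-defined")
    return np.linalg.solve(M, b)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two vectors, in [0, 180]."""
    c = float(np.clip(unit(u) @ unit(v), -1.0, 1.0))
    return float(np.rad2deg(np.arccos(c)))


def wrap_angle_deg(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle difference to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)
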
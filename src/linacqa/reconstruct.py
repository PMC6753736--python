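"""Recovery of linac geometry from noisy EPID measurement records.

The chain, per image: resect a pinhole camera (radiation source + detector
plane with its in-plane frame) from the known table-module marker geometry
and its 2D observations, then estimate the rigid pose of the head module by
perspective-n-point.  Per gantry angle: fit the collimator rotation axis from
the head-module marker configurations across collimator angles.  Globally:
the isocenter is the least-squares closest point to the collimator axes, and
the gantry rotation axis is the extrinsic mean of the axes of the optimal
rotations between consecutive gantry-angle point collections.

The reference frame of every reconstructed quantity is the frame in which
the table-module marker coordinates are expressed (the room frame in
simulation).  Truth blocks carried by image records are never read here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .errors import DegenerateGeometryError, ReconstructionError
from .phantom import PhantomModule
from .simulate import ImageRecord

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])

#: Relative cost-decrease tolerance and iteration cap of the Gauss-Newton refiners.
GN_TOL = 1e-10
GN_MAX_ITER = 200


# ---------------------------------------------------------------------------
# camera model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: source position plus detector plane with 2D frame.

    ``orientation`` is a proper rotation whose rows are the detector in-plane
    axes ``e_u``, ``e_v`` and the cross product ``e_u x e_v``; the viewing
    direction (source toward detector) is ``-orientation[2]``.  ``focal`` is
    the source-to-detector-plane distance (the SDD estimate) and
    ``principal`` the 2D coordinates of the foot of the perpendicular from
    the source.
    """

    source: np.ndarray
    orientation: np.ndarray
    focal: float
    principal: tuple[float, float]
    rms_residual: float = 0.0

    @property
    def e_u(self) -> np.ndarray:
        return self.orientation[0]

    @property
    def e_v(self) -> np.ndarray:
        return self.orientation[1]

    @property
    def view_dir(self) -> np.ndarray:
        return -self.orientation[2]

    @property
    def detector(self) -> geo.DetectorFrame:
        u0, v0 = self.principal
        origin = self.source + self.focal * self.view_dir - u0 * self.e_u - v0 * self.e_v
        return geo.DetectorFrame(origin=origin, e_u=self.e_u, e_v=self.e_v)

    def project(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d = p - self.source
        w = d @ self.view_dir
        if np.any(w <= 0):
            raise DegenerateGeometryError("point behind the camera")
        u = self.focal * (d @ self.e_u) / w + self.principal[0]
        v = self.focal * (d @ self.e_v) / w + self.principal[1]
        uv = np.stack([u, v], axis=-1)
        return uv if np.asarray(points).ndim == 2 else uv[0]


def _projection_residual_jacobian(cam_vecs, f, u0, v0, X, obs):
    """Residuals and per-point partials of the pinhole projection.

    Returns (residual vector 2n, du/dX and dv/dX rows (n,3), projections).
    """
    e_u, e_v, vdir, S = cam_vecs
    d = X - S
    w = d @ vdir
    cu = d @ e_u
    cv = d @ e_v
    if np.any(w <= 1e-9):
        # degenerate candidate (point at/behind the source); poison the cost
        bad = np.full(2 * len(X), np.inf)
        return bad, None, None, (cu, cv, w)
    u = f * cu / w + u0
    v = f * cv / w + v0
    res = np.concatenate([u - obs[:, 0], v - obs[:, 1]])
    w2 = w * w
    du_dX = f * (np.outer(1.0 / w, e_u) - (cu / w2)[:, None] * vdir)
    dv_dX = f * (np.outer(1.0 / w, e_v) - (cv / w2)[:, None] * vdir)
    return res, du_dX, dv_dX, (cu, cv, w)


def _rodrigues(delta: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(delta)
    if angle < 1e-15:
        return np.eye(3)
    return geo.rotation_matrix(delta / angle, np.rad2deg(angle))


# ---------------------------------------------------------------------------
# camera resection (direct linear transform + refinement)
# ---------------------------------------------------------------------------


def _dlt(X: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Direct linear transform: 3x4 projective camera from >= 6 points."""
    n = X.shape[0]
    Xh = np.hstack([X, np.ones((n, 1))])
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -uv[:, :1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -uv[:, 1:] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    w = Xh @ P[2]
    if np.mean(np.sign(w)) < 0:
        P = -P
    return P


def _decompose_projective(P: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Source, proper orientation, focal and principal point from a DLT camera."""
    from scipy.linalg import rq

    M = P[:, :3]
    center = np.linalg.solve(M, -P[:, 3])
    K, R = rq(M)
    D = np.diag(np.sign(np.diag(K)))
    K = K @ D
    R = D @ R
    K = K / K[2, 2]
    f = 0.5 * (K[0, 0] + K[1, 1])
    u0, v0 = K[0, 2], K[1, 2]
    # the detector 2D frame is left-handed w.r.t. the viewing direction, so a
    # proper orientation stores (e_u, e_v, e_u x e_v) with view = -row3
    Q = np.vstack([R[0], R[1], -R[2]])
    U, _, Vt = np.linalg.svd(Q)
    Q = U @ Vt
    if np.linalg.det(Q) < 0:
        Q = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return center, Q, float(f), float(u0), float(v0)


def _levenberg_marquardt(state, residual_fn, jacobian_fn, retract_fn):
    """Damped least squares with Marquardt scaling over a manifold state.

    ``retract_fn(state, step)`` applies a parameter step (rotations via the
    exponential map).  Returns the refined state and the RMS residual.
    """
    res = residual_fn(state)
    cost = res @ res
    if not np.isfinite(cost):
        raise ReconstructionError("refinement started from a degenerate state")
    lam = 1e-10
    for _ in range(GN_MAX_ITER):
        J = jacobian_fn(state)
        JtJ = J.T @ J
        Jtr = J.T @ res
        D = np.diag(np.maximum(np.diag(JtJ), 1e-12))
        improved = False
        for _ in range(25):
            try:
                step = np.linalg.solve(JtJ + lam * D, -Jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = retract_fn(state, step)
            cand_res = residual_fn(cand)
            cand_cost = cand_res @ cand_res
            if np.isfinite(cand_cost) and cand_cost <= cost:
                improved = True
                break
            lam *= 10.0
        if not improved:
            break
        rel_drop = (cost - cand_cost) / max(cost, 1e-300)
        state, res, cost = cand, cand_res, cand_cost
        lam = max(lam * 0.3, 1e-12)
        if rel_drop < GN_TOL:
            break
    return state, float(np.sqrt(cost / len(res)))


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product for (n, 3) arrays (fast path, no broadcasting)."""
    out = np.empty_like(b)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _refine_camera(S, Q, f, u0, v0, X, obs, fit_principal=False):
    """Damped least squares over the physical camera parameters.

    By default the principal point stays fixed: EPID coordinates are measured
    relative to the calibrated piercing point of the beam central axis, so
    only source (3), orientation (3) and focal length (1) are free.
    """
    n = X.shape[0]
    cols = list(range(9)) if fit_principal else list(range(7))

    def residual(st):
        S_, Q_, f_, u0_, v0_ = st
        res, *_ = _projection_residual_jacobian((Q_[0], Q_[1], -Q_[2], S_), f_, u0_, v0_, X, obs)
        return res

    def jacobian(st):
        S_, Q_, f_, u0_, v0_ = st
        e_u, e_v, vdir = Q_[0], Q_[1], -Q_[2]
        _, du_dX, dv_dX, (cu, cv, w) = _projection_residual_jacobian(
            (e_u, e_v, vdir, S_), f_, u0_, v0_, X, obs
        )
        d = X - S_
        w2 = (w * w)[:, None]
        # rows of Q rotate as q -> q + delta x q
        du_dR = f_ * (_cross_rows(np.tile(e_u, (n, 1)), d) * w[:, None] - cu[:, None] * _cross_rows(np.tile(vdir, (n, 1)), d)) / w2
        dv_dR = f_ * (_cross_rows(np.tile(e_v, (n, 1)), d) * w[:, None] - cv[:, None] * _cross_rows(np.tile(vdir, (n, 1)), d)) / w2
        J = np.zeros((2 * n, 9))
        J[:n, 0:3] = -du_dX
        J[n:, 0:3] = -dv_dX
        J[:n, 3:6] = du_dR
        J[n:, 3:6] = dv_dR
        J[:n, 6] = cu / w
        J[n:, 6] = cv / w
        J[:n, 7] = 1.0
        J[n:, 8] = 1.0
        return J[:, cols]

    def retract(st, step):
        full = np.zeros(9)
        full[cols] = step
        S_, Q_, f_, u0_, v0_ = st
        # rows of Q rotate in the world frame: q -> exp(delta^) q, i.e. Q -> Q R^T
        return (
            S_ + full[0:3],
            Q_ @ _rodrigues(full[3:6]).T,
            f_ + full[6],
            u0_ + full[7],
            v0_ + full[8],
        )

    (S, Q, f, u0, v0), rms = _levenberg_marquardt((S, Q, f, u0, v0), residual, jacobian, retract)
    return S, Q, f, u0, v0, rms


def nominal_camera(theta: float, psi: float, machine) -> CameraModel:
    """The camera of the nominal machine state at one plan element."""
    from .simulate import nominal_state

    st = nominal_state(theta, psi, machine)
    e_u, e_v = st.detector.e_u, st.detector.e_v
    Q = np.vstack([e_u, e_v, np.cross(e_u, e_v)])
    return CameraModel(source=st.source, orientation=Q, focal=machine.sdd, principal=(0.0, 0.0))


def resect_camera(
    image: ImageRecord,
    table_geometry: PhantomModule,
    init: CameraModel | None = None,
    fit_principal: bool = False,
) -> CameraModel:
    """Source position and detector plane from the table-module observations.

    The reprojection error is minimized by damped least squares over the
    physical camera parameters: source position (3), detector orientation (3)
    and focal length (1).  EPID image coordinates are referenced to the
    calibrated piercing point of the beam central axis, so the principal
    point is fixed unless ``fit_principal`` is set.  With ``init=None`` the
    start point comes from a closed-form DLT; in routine QA use the nominal
    machine state (known commanded angles and constants) is the natural start
    point and is considerably more reliable, because six markers grouped in
    two parallel planes sit close to a critical configuration of the
    projective resection problem.
    """
    X = table_geometry.parent_centers()
    obs = np.asarray(image.table_uv, dtype=float)
    if X.shape[0] < 6:
        raise ReconstructionError("camera resection needs >= 6 table markers")
    if obs.shape[0] != X.shape[0]:
        raise ReconstructionError("observation/marker count mismatch")
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-6 * sv[0]:
        raise ReconstructionError("table markers are (near-)coplanar; resection is degenerate")
    if init is None:
        P = _dlt(X, obs)
        S, Q, f, u0, v0 = _decompose_projective(P)
        if not fit_principal:
            u0 = v0 = 0.0
    else:
        S, Q, f = init.source.copy(), init.orientation.copy(), init.focal
        u0, v0 = init.principal
    S, Q, f, u0, v0, rms = _refine_camera(S, Q, f, u0, v0, X, obs, fit_principal=fit_principal)
    if not np.isfinite(rms):
        raise ReconstructionError("camera refinement did not converge")
    return CameraModel(source=S, orientation=Q, focal=f, principal=(u0, v0), rms_residual=rms)


# ---------------------------------------------------------------------------
# head-module pose (perspective-n-point)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseEstimate:
    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation


def _posit(Zrel: np.ndarray, xy: np.ndarray, n_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Classical POSIT (non-coplanar object): pose in normalized camera coords.

    ``Zrel`` are object points relative to the first point; ``xy`` the
    normalized image coordinates.  Returns (R, T) with camera coords
    ``c = R z + T`` for object coords relative to point 0.
    """
    B = np.linalg.pinv(Zrel)
    eps = np.zeros(len(Zrel))
    R = np.eye(3)
    Tz = None
    for _ in range(n_iter):
        rhs_x = xy[:, 0] * (1.0 + eps) - xy[0, 0]
        rhs_y = xy[:, 1] * (1.0 + eps) - xy[0, 1]
        Ivec = B @ rhs_x
        Jvec = B @ rhs_y
        nI, nJ = np.linalg.norm(Ivec), np.linalg.norm(Jvec)
        if nI < 1e-12 or nJ < 1e-12:
            raise ReconstructionError("POSIT failed: degenerate image configuration")
        s = 0.5 * (nI + nJ)
        r1 = Ivec / nI
        r2 = Jvec / nJ
        r3 = np.cross(r1, r2)
        R = np.vstack([r1, r2, r3])
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        Tz = 1.0 / s
        new_eps = (Zrel @ R[2]) / Tz
        if np.max(np.abs(new_eps - eps)) < 1e-12:
            eps = new_eps
            break
        eps = new_eps
    T = np.array([xy[0, 0] * Tz, xy[0, 1] * Tz, Tz])
    return R, T


def _refine_pose(Rp, tp, camera: CameraModel, Z, obs):
    """Damped least squares over the 6 rigid-pose parameters, full perspective model."""
    cam_vecs = (camera.e_u, camera.e_v, camera.view_dir, camera.source)
    f = camera.focal
    u0, v0 = camera.principal
    n = Z.shape[0]

    def residual(st):
        R_, t_ = st
        res, *_ = _projection_residual_jacobian(cam_vecs, f, u0, v0, Z @ R_.T + t_, obs)
        return res

    def jacobian(st):
        R_, t_ = st
        X = Z @ R_.T + t_
        _, du_dX, dv_dX, _ = _projection_residual_jacobian(cam_vecs, f, u0, v0, X, obs)
        RZ = Z @ R_.T
        J = np.zeros((2 * n, 6))
        # d(proj)/d(delta) = d(proj)/dX . (delta x RZ) = -d(proj)/dX . skew(RZ)
        J[:n, 0:3] = -_cross_rows(du_dX, RZ)
        J[n:, 0:3] = -_cross_rows(dv_dX, RZ)
        J[:n, 3:6] = du_dX
        J[n:, 3:6] = dv_dX
        return J

    def retract(st, step):
        R_, t_ = st
        return _rodrigues(step[0:3]) @ R_, t_ + step[3:6]

    (Rp, tp), rms = _levenberg_marquardt((Rp, tp), residual, jacobian, retract)
    return Rp, tp, rms


def nominal_module_pose(theta: float, psi: float, coll_geometry: PhantomModule) -> tuple[np.ndarray, np.ndarray]:
    """Nominal rigid pose (module-local -> room) of the head module."""
    from .simulate import gantry_rotation, nominal_state

    st = nominal_state(theta, psi)
    Rg = gantry_rotation(psi)
    Rc = geo.rotation_matrix(st.beam_direction, theta)
    M = Rc @ Rg
    return M @ coll_geometry.pose_rotation, M @ coll_geometry.pose_translation


def estimate_module_pose(
    image: ImageRecord,
    camera: CameraModel,
    coll_geometry: PhantomModule,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> PoseEstimate:
    """Rigid pose of the head module from its 2D observations under a known camera.

    A full-perspective damped-least-squares fit of the 6 pose parameters,
    started either from the supplied initial pose (nominal machine state in
    routine QA) or, when ``init=None``, from POSIT — the classical
    scaled-orthographic iteration, an excellent approximation here since the
    module is small compared with its distance from the source.
    """
    Z = coll_geometry.local_centers()
    obs = np.asarray(image.coll_uv, dtype=float)
    if Z.shape[0] < 4:
        raise ReconstructionError("pose estimation needs >= 4 head markers")
    if obs.shape[0] != Z.shape[0]:
        raise ReconstructionError("observation/marker count mismatch")
    if init is None:
        # right-handed normalized camera frame (e_u, -e_v, view); flip v accordingly
        u0, v0 = camera.principal
        xy = np.stack([(obs[:, 0] - u0) / camera.focal, -(obs[:, 1] - v0) / camera.focal], axis=1)
        Zrel = Z - Z[0]
        R_cam, T_cam = _posit(Zrel, xy)
        F = np.vstack([camera.e_u, -camera.e_v, camera.view_dir])
        Rp = F.T @ R_cam
        tp = camera.source + F.T @ T_cam - Rp @ Z[0]
    else:
        Rp, tp = init[0].copy(), init[1].copy()
    Rp, tp, rms = _refine_pose(Rp, tp, camera, Z, obs)
    return PoseEstimate(rotation=Rp, translation=tp, rms_residual=rms)


# ---------------------------------------------------------------------------
# axes, isocenter, scalar geometry
# ---------------------------------------------------------------------------


def estimate_collimator_axis(
    marker_sets: list[np.ndarray], reference_direction: np.ndarray
) -> geo.Line3:
    """Collimator rotation axis from head-marker configurations across angles.

    Consecutive configurations are related by rotations about the (common)
    axis: fit each pairwise rigid motion (Kabsch), take the extrinsic mean of
    the rotation axes for the direction, and anchor the line on the joint
    least-squares fixed point of all pairwise motions.  The direction is
    canonicalized toward ``reference_direction`` (module toward source).
    """
    if len(marker_sets) < 2:
        raise ReconstructionError("need >= 2 collimator angles to fit the axis")
    dirs = []
    rows = []
    rhs = []
    for A, B in zip(marker_sets[:-1], marker_sets[1:]):
        R, t = geo.rigid_transform(A, B)
        try:
            axis, _ = geo.rotation_axis_of(R, reference_direction)
        except DegenerateGeometryError as exc:
            raise ReconstructionError("rotation between collimator angles is near-identity") from exc
        dirs.append(axis)
        rows.append(np.eye(3) - R)
        rhs.append(t)
    direction = geo.extrinsic_mean_directions(np.array(dirs))
    anchor, *_ = np.linalg.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=1e-8)
    return geo.Line3(anchor, direction)


def estimate_isocenter(axes: list[geo.Line3]) -> np.ndarray:
    """Isocenter: the point minimizing summed squared distances to the axes."""
    return geo.closest_point_to_lines(axes)


def estimate_gantry_axis(collections: list[np.ndarray], reference: np.ndarray = _Y) -> np.ndarray:
    """Gantry rotation axis from corresponding point collections per gantry angle.

    Each collection holds the reconstructed head-marker and source positions
    at one gantry angle (table markers are excluded: they do not rotate).
    """
    if len(collections) < 2:
        raise ReconstructionError("need >= 2 gantry angles to fit the gantry axis")
    dirs = []
    for A, B in zip(collections[:-1], collections[1:]):
        R = geo.optimal_rotation(A, B)
        try:
            axis, _ = geo.rotation_axis_of(R, reference)
        except DegenerateGeometryError as exc:
            raise ReconstructionError("rotation between gantry angles is near-identity") from exc
        dirs.append(axis)
    return geo.extrinsic_mean_directions(np.array(dirs))


def estimate_gantry_angle(axis: geo.Line3, source_side: np.ndarray, vertical: np.ndarray = _Z) -> tuple[float, float]:
    """Angle between the collimator axis and the local vertical.

    The axis direction is canonicalized to point from the isocenter toward
    the source (``source_side`` gives that hemisphere).  Returns the
    unsigned angle in [0, 180] and a signed version (sign of the direction's
    X component) comparable to the nominal gantry angle.
    """
    d = axis.direction if axis.direction @ source_side >= 0 else -axis.direction
    ang = geo.angle_between(d, vertical)
    signed = ang if d[0] >= 0 else -ang
    return ang, signed


def estimate_sad(source: np.ndarray, axis: geo.Line3, isocenter: np.ndarray) -> float:
    """Distance from the source to its projection on the plane normal to the
    collimator axis through the isocenter."""
    return float(abs((np.asarray(source) - isocenter) @ axis.direction))


def estimate_sdd(source: np.ndarray, detector_plane: geo.Plane3) -> float:
    """Unsigned source-to-detector-plane distance."""
    return float(abs(detector_plane.signed_distance(np.asarray(source))))


# ---------------------------------------------------------------------------
# radiation-field reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldReconstruction:
    """Field corners back-projected into the isocentric plane H."""

    corners: np.ndarray  # (4, 3), order A, B, C, D
    edge_lengths: np.ndarray  # (4,) AB, BC, CD, DA
    corner_angles: np.ndarray  # (4,) deg, ABC, BCD, CDA, DAB
    corner_deviations: np.ndarray | None = None  # (4,) cm from nominal corners


def reconstruct_field(
    corner_uv: np.ndarray,
    camera: CameraModel,
    axis: geo.Line3,
    isocenter: np.ndarray,
    nominal_corners: np.ndarray | None = None,
) -> FieldReconstruction:
    """Back-project the 4 detector field corners to the plane normal to the
    collimator axis through the isocenter; report edge lengths and angles."""
    H = geo.Plane3(isocenter, axis.direction)
    det = camera.detector
    pts3d = det.to_3d(np.asarray(corner_uv, dtype=float))
    corners = np.array(
        [geo.line_plane_intersection(geo.Line3(camera.source, p - camera.source), H) for p in pts3d]
    )
    nxt = np.roll(corners, -1, axis=0)
    edges = np.linalg.norm(nxt - corners, axis=1)
    # angle at corner k+1 between (k -> k+1) and (k+1 -> k+2): ABC at B, ...
    angles = np.empty(4)
    for k in range(4):
        b = corners[(k + 1) % 4]
        a = corners[k]
        c = corners[(k + 2) % 4]
        angles[k] = geo.angle_between(a - b, c - b)
    dev = None
    if nominal_corners is not None:
        dev = np.linalg.norm(corners - np.asarray(nominal_corners), axis=1)
    return FieldReconstruction(corners=corners, edge_lengths=edges, corner_angles=angles, corner_deviations=dev)


# ---------------------------------------------------------------------------
# full-plan driver
# ---------------------------------------------------------------------------


@dataclass
class ReconstructedGeometry:
    """All estimates recovered from one replicate of a test plan."""

    gantry_angles: list[float]  # nominal labels, plan order
    collimator_axes: list[geo.Line3]  # one per gantry angle
    vertical_angles: list[float]  # unsigned axis-vs-vertical angle per gantry angle
    vertical_angles_signed: list[float]
    isocenter: np.ndarray
    gantry_axis: np.ndarray
    image_theta: np.ndarray
    image_psi: np.ndarray
    image_sad: np.ndarray  # per image, cm
    image_sdd: np.ndarray  # per image, cm
    fields: list[FieldReconstruction] = field(default_factory=list)
    cameras: list[CameraModel] = field(default_factory=list)
    poses: list[PoseEstimate] = field(default_factory=list)

    def diagnostics(self) -> list[dict]:
        """Per-image fit diagnostics (residuals), one row per image."""
        rows = []
        for i in range(len(self.image_theta)):
            rows.append(
                {
                    "theta_deg": float(self.image_theta[i]),
                    "psi_deg": float(self.image_psi[i]),
                    "camera_rms_cm": self.cameras[i].rms_residual if self.cameras else None,
                    "pose_rms_cm": self.poses[i].rms_residual if self.poses else None,
                    "sad_cm": float(self.image_sad[i]),
                    "sdd_cm": float(self.image_sdd[i]),
                }
            )
        return rows

    def to_dict(self) -> dict:
        return {
            "gantry_angles_deg": list(self.gantry_angles),
            "isocenter_cm": self.isocenter.tolist(),
            "gantry_axis": self.gantry_axis.tolist(),
            "vertical_angles_deg": list(self.vertical_angles),
            "vertical_angles_signed_deg": list(self.vertical_angles_signed),
            "collimator_axes": [
                {"point_cm": ax.point.tolist(), "direction": ax.direction.tolist()}
                for ax in self.collimator_axes
            ],
            "image_theta_deg": self.image_theta.tolist(),
            "image_psi_deg": self.image_psi.tolist(),
            "sad_cm": self.image_sad.tolist(),
            "sdd_cm": self.image_sdd.tolist(),
            "field_edge_lengths_cm": [f.edge_lengths.tolist() for f in self.fields],
            "field_corner_angles_deg": [f.corner_angles.tolist() for f in self.fields],
        }


def reconstruct_plan(
    records: list[ImageRecord],
    table_geometry: PhantomModule,
    coll_geometry: PhantomModule,
    machine=None,
    include_sources: bool = True,
    nominal_corner_fn=None,
) -> ReconstructedGeometry:
    """Run the full reconstruction chain on the records of one plan replicate.

    ``machine`` (the nominal constants, known from the commanded plan) seeds
    the per-image camera and pose refinements; without it the closed-form
    initializers are used.  ``nominal_corner_fn(theta, psi) -> (4, 3)``
    optionally supplies nominal field corners for corner-deviation reporting.
    ``include_sources`` controls whether resected source positions join the
    head-marker collections used for gantry-axis estimation.
    """
    if not records:
        raise ReconstructionError("no records")
    # group images by gantry angle, preserving plan order
    by_psi: dict[float, list[int]] = {}
    for i, rec in enumerate(records):
        by_psi.setdefault(rec.psi, []).append(i)
    if len(by_psi) < 2:
        raise ReconstructionError("need >= 2 gantry angles to reconstruct the isocenter")

    if machine is not None:
        cameras = [
            resect_camera(rec, table_geometry, init=nominal_camera(rec.theta, rec.psi, machine))
            for rec in records
        ]
        poses = [
            estimate_module_pose(
                rec, cam, coll_geometry, init=nominal_module_pose(rec.theta, rec.psi, coll_geometry)
            )
            for rec, cam in zip(records, cameras)
        ]
    else:
        cameras = [resect_camera(rec, table_geometry) for rec in records]
        poses = [estimate_module_pose(rec, cam, coll_geometry) for rec, cam in zip(records, cameras)]
    Z = coll_geometry.local_centers()

    gantry_angles: list[float] = []
    axes: list[geo.Line3] = []
    collections: list[np.ndarray] = []
    for psi, idxs in by_psi.items():
        if len(idxs) < 2:
            raise ReconstructionError(f"need >= 2 collimator angles at gantry angle {psi}")
        marker_sets = [poses[i].apply(Z) for i in idxs]
        sources = np.array([cameras[i].source for i in idxs])
        ref = sources.mean(axis=0) - np.mean(np.vstack(marker_sets), axis=0)
        axes.append(estimate_collimator_axis(marker_sets, ref))
        gantry_angles.append(psi)
        coll_pts = np.vstack(marker_sets)
        collections.append(np.vstack([coll_pts, sources]) if include_sources else coll_pts)

    isocenter = estimate_isocenter(axes)
    gantry_axis = estimate_gantry_axis(collections)

    vertical_angles: list[float] = []
    vertical_angles_signed: list[float] = []
    psi_axis = {}
    for psi, ax in zip(gantry_angles, axes):
        idx0 = by_psi[psi][0]
        ang, signed = estimate_gantry_angle(ax, cameras[idx0].source - isocenter)
        vertical_angles.append(ang)
        vertical_angles_signed.append(signed)
        psi_axis[psi] = ax

    n = len(records)
    image_sad = np.empty(n)
    image_sdd = np.empty(n)
    fields = []
    for i, rec in enumerate(records):
        ax = psi_axis[rec.psi]
        image_sad[i] = estimate_sad(cameras[i].source, ax, isocenter)
        image_sdd[i] = estimate_sdd(cameras[i].source, cameras[i].detector.plane)
        nom = nominal_corner_fn(rec.theta, rec.psi) if nominal_corner_fn is not None else None
        fields.append(reconstruct_field(rec.corner_uv, cameras[i], ax, isocenter, nom))

    return ReconstructedGeometry(
        gantry_angles=gantry_angles,
        collimator_axes=axes,
        vertical_angles=vertical_angles,
        vertical_angles_signed=vertical_angles_signed,
        isocenter=isocenter,
        gantry_axis=gantry_axis,
        image_theta=np.array([r.theta for r in records]),
        image_psi=np.array([r.psi for r in records]),
        image_sad=image_sad,
        image_sdd=image_sdd,
        fields=fields,
        cameras=cameras,
        poses=poses,
    )
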
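"""Forward projection of the phantom onto the EPID plane with Gaussian noise.

For every (collimator angle, gantry angle) pair of a test plan the simulator
places the machine in its nominal state, projects the marker centers and the
four field corners onto the detector, and perturbs every measured 2D
coordinate with i.i.d. Gaussian noise of standard deviation sigma (given in
mm, applied in cm).  Each image record carries a truth block for diagnostics;
the reconstruction stack never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .errors import VisibilityError
from .phantom import EPID_HALF_SIZE, PhantomModule
from .plan import MachineConstants, TestPlan

_Y = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class NominalState:
    """Exact machine geometry at one (collimator, gantry) angle pair."""

    theta: float
    psi: float
    machine: MachineConstants
    source: np.ndarray
    beam_direction: np.ndarray  # unit, source -> isocenter
    detector: geo.DetectorFrame
    collimator_axis: geo.Line3
    field_corners: np.ndarray  # (4, 3), corners A..D in the isocentric plane
    field_axes: tuple[np.ndarray, np.ndarray]  # in-plane axes rotated by theta

    def project(self, points: np.ndarray) -> np.ndarray:
        return geo.central_projection(self.source, self.detector, points)


def gantry_rotation(psi: float) -> np.ndarray:
    """Gantry rotation matrix: +psi moves the source from +Z toward +X."""
    return geo.rotation_matrix(_Y, psi)


def nominal_state(theta: float, psi: float, machine: MachineConstants | None = None) -> NominalState:
    """Nominal source, detector, collimator axis and field corners.

    The detector plane is normal to the beam axis at SDD beyond the source;
    its 2D frame co-rotates with the gantry but not with the collimator.
    Field corners live in the isocentric plane and rotate with the collimator.
    """
    machine = machine or MachineConstants()
    Rg = gantry_rotation(psi)
    source = Rg @ np.array([0.0, 0.0, machine.sad])
    beam = -source / machine.sad
    e_u = Rg @ np.array([1.0, 0.0, 0.0])
    e_v = _Y
    det_origin = source + machine.sdd * beam
    detector = geo.DetectorFrame(origin=det_origin, e_u=e_u, e_v=e_v)
    Rc = geo.rotation_matrix(beam, theta)
    f1 = Rc @ e_u
    f2 = Rc @ e_v
    hu, hv = machine.field_size[0] / 2.0, machine.field_size[1] / 2.0
    # corners A, B, C, D in consecutive order around the square
    signs = np.array([(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)])
    corners = signs[:, :1] * (hu * f1) + signs[:, 1:] * (hv * f2)
    return NominalState(
        theta=float(theta),
        psi=float(psi),
        machine=machine,
        source=source,
        beam_direction=beam,
        detector=detector,
        collimator_axis=geo.Line3(source, beam),
        field_corners=corners,
        field_axes=(f1, f2),
    )


def marker_world_positions(
    theta: float,
    psi: float,
    table: PhantomModule,
    collimator: PhantomModule,
    machine: MachineConstants | None = None,
) -> np.ndarray:
    """Room-frame marker centers, table module first then head module.

    Table markers are fixed in the room frame.  Head markers are expressed in
    the collimator frame and undergo the collimator rotation (about the beam
    axis) composed with the gantry rotation.
    """
    machine = machine or MachineConstants()
    state = nominal_state(theta, psi, machine)
    Rg = gantry_rotation(psi)
    Rc = geo.rotation_matrix(state.beam_direction, theta)
    head = collimator.parent_centers() @ (Rc @ Rg).T
    return np.vstack([table.parent_centers(), head])


@dataclass(frozen=True)
class TruthBlock:
    """Noise-free projections and exact geometry, for diagnostics only."""

    table_uv: np.ndarray
    coll_uv: np.ndarray
    corner_uv: np.ndarray
    source: np.ndarray
    detector: geo.DetectorFrame
    marker_world: np.ndarray


@dataclass(frozen=True)
class ImageRecord:
    """One simulated EPID exposure: noisy 2D marker and field-corner coordinates."""

    theta: float
    psi: float
    table_ids: tuple[int, ...]
    coll_ids: tuple[int, ...]
    table_uv: np.ndarray  # (n_table, 2) cm
    coll_uv: np.ndarray  # (n_coll, 2) cm
    corner_uv: np.ndarray  # (4, 2) cm
    truth: TruthBlock | None = None

    def to_rows(self, replicate: int = 0) -> list[dict]:
        rows = []
        for module, ids, uv in (
            ("table", self.table_ids, self.table_uv),
            ("collimator", self.coll_ids, self.coll_uv),
        ):
            for mid, (u, v) in zip(ids, uv):
                rows.append(
                    {"replicate": replicate, "theta_deg": self.theta, "psi_deg": self.psi,
                     "module": module, "marker_id": mid, "u_cm": float(u), "v_cm": float(v)}
                )
        for c, (u, v) in zip("ABCD", self.corner_uv):
            rows.append(
                {"replicate": replicate, "theta_deg": self.theta, "psi_deg": self.psi,
                 "module": "field", "marker_id": c, "u_cm": float(u), "v_cm": float(v)}
            )
        return rows


def _check_visibility(
    state: NominalState,
    world: np.ndarray,
    n_table: int,
    epid_half_size: float = EPID_HALF_SIZE,
) -> None:
    machine = state.machine
    depth = (world - state.source) @ state.beam_direction
    head = world[n_table:] - state.source
    e1, e2 = state.field_axes
    half_u, half_v = machine.field_size[0] / 2.0, machine.field_size[1] / 2.0
    d_head = depth[n_table:]
    if np.any(np.abs(head @ e1) > (half_u / machine.sad) * d_head) or np.any(
        np.abs(head @ e2) > (half_v / machine.sad) * d_head
    ):
        raise VisibilityError(
            f"head marker outside the radiation field at (theta={state.theta}, psi={state.psi}); "
            "run phantom.validate_configuration for a full report"
        )
    uv = state.project(world[:n_table])
    if np.any(np.abs(uv) > epid_half_size):
        raise VisibilityError(
            f"table marker outside the EPID at (theta={state.theta}, psi={state.psi}); "
            "run phantom.validate_configuration for a full report"
        )


def simulate_image(
    theta: float,
    psi: float,
    table: PhantomModule,
    collimator: PhantomModule,
    machine: MachineConstants,
    sigma_mm: float,
    rng: np.random.Generator,
    check_visibility: bool = True,
    keep_truth: bool = True,
) -> ImageRecord:
    """Simulate one exposure: project all markers and corners, add noise."""
    state = nominal_state(theta, psi, machine)
    world = marker_world_positions(theta, psi, table, collimator, machine)
    n_table = table.n_markers
    if check_visibility:
        _check_visibility(state, world, n_table)
    uv = state.project(world)
    corner_uv = state.project(state.field_corners)
    sigma_cm = sigma_mm / 10.0
    if sigma_cm > 0:
        noisy = uv + rng.normal(0.0, sigma_cm, size=uv.shape)
        noisy_corners = corner_uv + rng.normal(0.0, sigma_cm, size=corner_uv.shape)
    else:
        noisy, noisy_corners = uv.copy(), corner_uv.copy()
    truth = (
        TruthBlock(
            table_uv=uv[:n_table],
            coll_uv=uv[n_table:],
            corner_uv=corner_uv,
            source=state.source,
            detector=state.detector,
            marker_world=world,
        )
        if keep_truth
        else None
    )
    return ImageRecord(
        theta=float(theta),
        psi=float(psi),
        table_ids=tuple(m.id for m in table.markers),
        coll_ids=tuple(m.id for m in collimator.markers),
        table_uv=noisy[:n_table],
        coll_uv=noisy[n_table:],
        corner_uv=noisy_corners,
        truth=truth,
    )


def image_rng(seed: int, replicate: int, image_index: int) -> np.random.Generator:
    """Deterministic per-image random stream: (seed, replicate, image) -> Generator."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate, image_index)))


def simulate_plan(
    plan: TestPlan,
    table: PhantomModule,
    collimator: PhantomModule,
    seed: int = 0,
    replicate: int = 0,
    check_visibility: bool = True,
    keep_truth: bool = True,
) -> list[ImageRecord]:
    """One image record per plan element, with per-image derived random streams."""
    records = []
    for idx, (theta, psi) in enumerate(plan.pairs):
        rng = image_rng(seed, replicate, idx)
        records.append(
            simulate_image(
                theta, psi, table, collimator, plan.machine, plan.sigma_mm, rng,
                check_visibility=check_visibility, keep_truth=keep_truth,
            )
        )
    return records


def records_to_rows(records: list[ImageRecord], replicate: int = 0) -> list[dict]:
    """Flatten image records to CSV-ready rows (one row per observation)."""
    rows: list[dict] = []
    for rec in records:
        rows.extend(rec.to_rows(replicate))
    return rows


def records_to_jsonl(records: list[ImageRecord], replicate: int = 0) -> str:
    """Serialize image records as JSON lines (one image per line)."""
    import json

    lines = []
    for rec in records:
        lines.append(
            json.dumps(
                {
                    "replicate": replicate,
                    "theta_deg": rec.theta,
                    "psi_deg": rec.psi,
                    "table": {str(i): uv.tolist() for i, uv in zip(rec.table_ids, rec.table_uv)},
                    "collimator": {str(i): uv.tolist() for i, uv in zip(rec.coll_ids, rec.coll_uv)},
                    "corners": rec.corner_uv.tolist(),
                }
            )
        )
    return "\n".join(lines) + "\n"
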
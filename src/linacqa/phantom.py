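"""Two-module fiducial-ball phantom: construction, validation, serialization.

The phantom has a table-mounted module (its markers stay fixed in the room
frame) and a collimator-mounted module (its markers co-rotate with the
collimator head and hence also with the gantry).  Marker centers are given in
a module-local frame; a rigid pose maps the module into its parent frame —
the room frame for the table module, the collimator frame (which coincides
with the room frame at zero gantry and collimator angles) for the head
module.

Layout generators are deterministic: the same arguments always produce the
same module.  Marker placement follows the usual practice for this kind of
phantom — markers grouped in parallel planes perpendicular to the beam-facing
axis, every marker at a distinct coordinate along the gantry rotation axis so
their projected disks stay apart at every gantry angle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .plan import MachineConstants, TestPlan

#: Default fiducial ball radius in cm.
DEFAULT_BALL_RADIUS = 0.3

#: Half-size (cm) of the sensitive EPID area used for visibility checks.
EPID_HALF_SIZE = 20.0

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class Mounting(enum.Enum):
    TABLE = "table"
    COLLIMATOR = "collimator"


#: Minimum marker counts exercised by the method (resection needs >= 6
#: non-coplanar table markers; pose estimation needs >= 4 head markers).
MIN_MARKERS = {Mounting.TABLE: 6, Mounting.COLLIMATOR: 4}


@dataclass(frozen=True)
class BallMarker:
    id: int
    center: np.ndarray  # module-local, cm
    radius: float = DEFAULT_BALL_RADIUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ConfigurationError("ball radius must be positive")


@dataclass(frozen=True)
class PhantomModule:
    mounting: Mounting
    markers: tuple[BallMarker, ...]
    pose_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    pose_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "pose_rotation", np.asarray(self.pose_rotation, dtype=float))
        object.__setattr__(self, "pose_translation", np.asarray(self.pose_translation, dtype=float))
        n_min = MIN_MARKERS[self.mounting]
        if len(self.markers) < n_min:
            raise ConfigurationError(
                f"{self.mounting.value} module needs >= {n_min} markers, got {len(self.markers)}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def radii(self) -> np.ndarray:
        return np.array([m.radius for m in self.markers])

    def local_centers(self) -> np.ndarray:
        return np.array([m.center for m in self.markers])

    def parent_centers(self) -> np.ndarray:
        """Marker centers in the parent frame (pose applied)."""
        return self.local_centers() @ self.pose_rotation.T + self.pose_translation

    def with_pose(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "PhantomModule":
        return PhantomModule(
            mounting=self.mounting,
            markers=self.markers,
            pose_rotation=self.pose_rotation if rotation is None else rotation,
            pose_translation=self.pose_translation if translation is None else translation,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mounting": self.mounting.value,
            "markers": [
                {"id": m.id, "center_cm": [float(x) for x in m.center], "radius_cm": m.radius}
                for m in self.markers
            ],
            "pose_rotation": self.pose_rotation.tolist(),
            "pose_translation_cm": self.pose_translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomModule":
        markers = tuple(
            BallMarker(id=int(m["id"]), center=m["center_cm"], radius=float(m.get("radius_cm", DEFAULT_BALL_RADIUS)))
            for m in d["markers"]
        )
        return cls(
            mounting=Mounting(d["mounting"]),
            markers=markers,
            pose_rotation=np.asarray(d.get("pose_rotation", np.eye(3))),
            pose_translation=np.asarray(d.get("pose_translation_cm", np.zeros(3))),
        )

    def centers_csv(self) -> str:
        lines = ["id,x_cm,y_cm,z_cm,radius_cm"]
        for m in self.markers:
            lines.append(f"{m.id},{m.center[0]:.6f},{m.center[1]:.6f},{m.center[2]:.6f},{m.radius:.6f}")
        return "\n".join(lines) + "\n"


def _stagger(i: int, phase: float = 0.0) -> float:
    """Deterministic low-discrepancy value in (-1, 1) for marker index ``i``."""
    return 2.0 * (((i + 1) * _GOLDEN + phase) % 1.0) - 1.0


def planar_layout(
    n_balls: int,
    max_per_plane: int,
    bounding_cube_edge: float,
    mounting: Mounting,
    ball_radius: float = DEFAULT_BALL_RADIUS,
) -> PhantomModule:
    """Markers in parallel planes perpendicular to the module z axis.

    Planes are spread uniformly across the cube; within each plane markers sit
    at staggered x positions.  Marker y coordinates (the gantry-axis
    direction) are evenly spaced across the cube so that every marker has a
    distinct y — the sufficient condition for projected disks not to overlap
    under gantry rotation.
    """
    if n_balls < MIN_MARKERS[mounting]:
        raise ConfigurationError(
            f"{mounting.value} module needs >= {MIN_MARKERS[mounting]} balls, got {n_balls}"
        )
    if max_per_plane < 1 or bounding_cube_edge <= 0:
        raise ConfigurationError("invalid layout parameters")
    half = bounding_cube_edge / 2.0
    inset = half - ball_radius
    if inset <= 0:
        raise ConfigurationError("bounding cube too small for the ball radius")

    n_planes = math.ceil(n_balls / max_per_plane)
    if n_planes == 1:
        z_planes = np.array([0.0])
    else:
        z_planes = np.linspace(-inset, inset, n_planes)
    # balanced assignment of markers to planes (sizes differ by at most 1)
    base, extra = divmod(n_balls, n_planes)
    plane_sizes = [base + (1 if j < extra else 0) for j in range(n_planes)]
    if max(plane_sizes) > max_per_plane:
        raise ConfigurationError("cannot pack markers with the given per-plane limit")

    # evenly spaced y plus a sub-half-gap stagger: keeps every y distinct while
    # breaking the exact regularity that makes resection ill-conditioned
    ys = np.linspace(-inset, inset, n_balls) if n_balls > 1 else np.array([0.0])
    if n_balls > 1:
        gap = ys[1] - ys[0]
        ys = ys + 0.35 * gap * np.array([_stagger(i, phase=0.11) for i in range(n_balls)])
        ys = np.clip(ys, -inset, inset)
    markers = []
    i = 0
    for j, size in enumerate(plane_sizes):
        for k in range(size):
            x = inset * 0.95 * _stagger(i, phase=0.37 * j)
            markers.append(BallMarker(id=i, center=np.array([x, ys[i], z_planes[j]]), radius=ball_radius))
            i += 1
    return PhantomModule(mounting=mounting, markers=tuple(markers))


def spiral_layout(
    n_balls: int,
    cuboid: tuple[float, float, float],
    axis: np.ndarray = (0.0, 1.0, 0.0),
    turns: float = 2.0,
    ball_radius: float = DEFAULT_BALL_RADIUS,
) -> PhantomModule:
    """Table-module markers along a helix whose axis is the gantry axis.

    ``cuboid`` is the (x, y, z) bounding extent in cm.  The helix advances
    monotonically along ``axis`` (must be the module +y for a table module)
    so every marker has a distinct gantry-axis coordinate.
    """
    if n_balls < 4:
        raise ConfigurationError("spiral layout needs at least 4 balls")
    axis = np.asarray(axis, dtype=float)
    if not np.allclose(axis / np.linalg.norm(axis), [0.0, 1.0, 0.0]):
        raise ConfigurationError("spiral axis must be the gantry-axis direction (0, 1, 0)")
    cx, cy, cz = (float(c) for c in cuboid)
    if min(cx, cy, cz) <= 2 * ball_radius:
        raise ConfigurationError("degenerate cuboid")
    a = cx / 2.0 - ball_radius
    b = cz / 2.0 - ball_radius
    ys = np.linspace(-(cy / 2.0 - ball_radius), cy / 2.0 - ball_radius, n_balls)
    phis = np.linspace(0.0, 2.0 * np.pi * turns, n_balls)
    markers = tuple(
        BallMarker(id=i, center=np.array([a * np.cos(p), y, b * np.sin(p)]), radius=ball_radius)
        for i, (y, p) in enumerate(zip(ys, phis))
    )
    return PhantomModule(mounting=Mounting.TABLE, markers=markers)


def baseline_table_module(n_balls: int = 6, cube_edge: float = 8.0) -> PhantomModule:
    """Table module of the reference configuration: n balls in an 8 cm cube."""
    return planar_layout(n_balls, max_per_plane=4, bounding_cube_edge=cube_edge, mounting=Mounting.TABLE)


#: Offset (cm) of the head-module center from the isocenter toward the source,
#: along the beam axis.  Places the module on the accessory mount of the
#: collimator head while keeping all markers inside the radiation field cone.
COLLIMATOR_MODULE_OFFSET = 35.0


def baseline_collimator_module(
    n_balls: int = 4, cube_edge: float = 6.0, beam_offset: float = COLLIMATOR_MODULE_OFFSET
) -> PhantomModule:
    """Head module of the reference configuration: n balls in a 6 cm cube."""
    mod = planar_layout(n_balls, max_per_plane=3, bounding_cube_edge=cube_edge, mounting=Mounting.COLLIMATOR)
    return mod.with_pose(translation=np.array([0.0, 0.0, beam_offset]))


# ---------------------------------------------------------------------------
# configuration validity
# ---------------------------------------------------------------------------


@dataclass
class ValidityReport:
    """Per-plan-element visibility and projected-disk-overlap violations."""

    outside: list[tuple[float, float, str]] = field(default_factory=list)
    overlaps: list[tuple[float, float, str, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.outside and not self.overlaps

    def __str__(self) -> str:
        if self.valid:
            return "configuration valid"
        parts = [f"{len(self.outside)} visibility violation(s), {len(self.overlaps)} overlap(s)"]
        for theta, psi, m in self.outside[:10]:
            parts.append(f"  outside at (theta={theta}, psi={psi}): {m}")
        for theta, psi, m1, m2 in self.overlaps[:10]:
            parts.append(f"  overlap at (theta={theta}, psi={psi}): {m1} vs {m2}")
        return "\n".join(parts)


def validate_configuration(
    table: PhantomModule,
    collimator: PhantomModule,
    plan: TestPlan,
    machine: MachineConstants | None = None,
    epid_half_size: float = EPID_HALF_SIZE,
) -> ValidityReport:
    """Check marker visibility and projected-disk separation over a whole plan.

    Head-module markers must lie inside the radiation-field cone (they are
    only imaged where the field irradiates the EPID); table-module markers
    must project inside the EPID sensitive area.  Any two projected marker
    disks (center projection, radius magnified by SDD/depth) must not overlap.
    """
    from .simulate import marker_world_positions, nominal_state  # deferred: avoids import cycle

    machine = machine or plan.machine
    if len(plan) == 0:
        raise ConfigurationError("plan is empty")
    report = ValidityReport()
    half_u = machine.field_size[0] / 2.0
    half_v = machine.field_size[1] / 2.0
    radii = np.concatenate([table.radii, collimator.radii])
    names = [f"table/{m.id}" for m in table.markers] + [f"coll/{m.id}" for m in collimator.markers]
    n_table = table.n_markers
    for theta, psi in plan.pairs:
        state = nominal_state(theta, psi, machine)
        world = marker_world_positions(theta, psi, table, collimator, machine)
        depth = (world - state.source) @ state.beam_direction
        # field-cone check for head markers, in the collimator-rotated frame
        coll_world = world[n_table:]
        e1, e2 = state.field_axes
        lat1 = (coll_world - state.source) @ e1
        lat2 = (coll_world - state.source) @ e2
        d_head = depth[n_table:]
        r_head = radii[n_table:]
        ok = (np.abs(lat1) <= (half_u / machine.sad) * d_head - r_head) & (
            np.abs(lat2) <= (half_v / machine.sad) * d_head - r_head
        )
        for idx in np.nonzero(~ok)[0]:
            report.outside.append((theta, psi, names[n_table + idx] + " outside field"))
        uv = state.project(world)
        mag = machine.sdd / depth
        proj_r = radii * mag
        on_epid = np.all(np.abs(uv) + proj_r[:, None] <= epid_half_size, axis=1)
        for idx in np.nonzero(~on_epid[:n_table])[0]:
            report.outside.append((theta, psi, names[idx] + " outside EPID"))
        # pairwise projected-disk overlap
        diff = uv[:, None, :] - uv[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        limit = proj_r[:, None] + proj_r[None, :]
        bad = np.triu(dist < limit, k=1)
        for i, j in zip(*np.nonzero(bad)):
            report.overlaps.append((theta, psi, names[i], names[j]))
    return report
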
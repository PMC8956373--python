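"""Synthetic CT phantoms, calibration pose pairs, and fiducial sets.

Every generator returns its ground truth alongside the data, so each stage of
the pipeline (segmentation, planning, calibration, registration) can be
validated by recovery rather than against copied fixtures. All generators are
pure functions of (spec, seed).

The default anatomy is a torso-scale ellipsoid of soft tissue in air, with
optional lung cavities, rib arcs, a spine cylinder, a detached arm cylinder
(an occluder), and a narrow "nostril" air channel that pierces the skin — the
structures that exercise each branch of the planner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform
from .volume_io import Volume, voxel_center_grid


class PhantomSpecError(ValueError):
    """Raised for inconsistent phantom specifications."""


class DegeneratePoseSetError(ValueError):
    """Raised when too few pose pairs are requested."""


@dataclass
class PhantomSpec:
    """Geometric description of a synthetic corpse.

    Lengths in mm, HU levels on the Hounsfield scale. Structures are placed
    relative to the grid center. Priority on overlap: steel > bone > lung >
    soft tissue > air; the nostril channel carves air at lung priority.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    torso_half_axes: tuple[float, float, float] = (70.0, 55.0, 85.0)
    hu_air: float = -1000.0
    hu_lung: float = -800.0
    hu_soft: float = 40.0
    hu_bone: float = 700.0
    hu_steel: float = 3000.0
    lung_half_axes: tuple[float, float, float] | None = None  # pair of cavities if set
    lung_offset_x: float = 28.0
    rib_count: int = 0
    rib_radius: float = 46.0
    rib_thickness: float = 6.0  # tube diameter
    rib_arc_deg: float = 120.0  # anterior arc span, centered on +y
    rib_z_pitch: float = 16.0
    spine_radius: float = 0.0
    arm_offset: tuple[float, float] | None = None  # (x, y) offset of arm axis from center
    arm_radius: float = 0.0
    arm_half_length: float = 70.0
    nostril_diameter: float = 0.0  # < 10 mm so a 1 cm closing seals it
    nostril_offset_x: float = 0.0
    targets: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        hu = [self.hu_air, self.hu_lung, self.hu_soft, self.hu_bone, self.hu_steel]
        if not all(a < b for a, b in zip(hu, hu[1:])):
            raise PhantomSpecError("HU levels must be strictly ordered air < lung < soft < bone < steel")
        if self.nostril_diameter >= 10.0:
            raise PhantomSpecError("nostril channel must be narrower than the 1 cm closing kernel")
        half_extent = 0.5 * np.array(self.spacing) * np.array(self.shape)
        if np.any(np.array(self.torso_half_axes) >= half_extent):
            raise PhantomSpecError("torso does not fit inside the grid")

    @property
    def center(self) -> np.ndarray:
        """World position of the grid center (origin at 0, identity direction)."""
        return 0.5 * (np.array(self.shape) - 1) * np.array(self.spacing)


@dataclass
class PhantomData:
    """A rendered phantom: HU volume plus voxel-exact analytic masks."""

    volume: Volume
    body_mask: np.ndarray  # torso only (what skin segmentation should recover)
    structures: dict[str, np.ndarray]  # lung, bone, arm, nostril, body_with_arm ...
    spec: PhantomSpec


def _ellipsoid(px, py, pz, center, half_axes) -> np.ndarray:
    a, b, c = half_axes
    return ((px - center[0]) / a) ** 2 + ((py - center[1]) / b) ** 2 + ((pz - center[2]) / c) ** 2 <= 1.0


def _cylinder_z(px, py, pz, axis_xy, radius, z_center, half_length) -> np.ndarray:
    r2 = (px - axis_xy[0]) ** 2 + (py - axis_xy[1]) ** 2
    return (r2 <= radius**2) & (np.abs(pz - z_center) <= half_length)


def _rib_arcs(px, py, pz, center, spec: PhantomSpec) -> np.ndarray:
    """Anterior torus-segment arcs in axial planes, stacked along z."""
    mask = np.zeros(px.shape, dtype=bool)
    tube_r = spec.rib_thickness / 2.0
    half_arc = np.radians(spec.rib_arc_deg) / 2.0
    z0 = center[2] - 0.5 * (spec.rib_count - 1) * spec.rib_z_pitch
    dx, dy = px - center[0], py - center[1]
    r_xy = np.sqrt(dx**2 + dy**2)
    phi = np.arctan2(dx, dy)  # 0 at +y (anterior)
    in_arc = np.abs(phi) <= half_arc
    for i in range(spec.rib_count):
        zc = z0 + i * spec.rib_z_pitch
        dist = np.sqrt((r_xy - spec.rib_radius) ** 2 + (pz - zc) ** 2)
        mask |= (dist <= tube_r) & in_arc
    return mask


def make_phantom(spec: PhantomSpec) -> PhantomData:
    """Rasterize the spec into an HU volume with analytic ground-truth masks.

    A voxel belongs to a primitive iff its center is inside the primitive, so
    the masks are the exact rasterization of the geometry.
    """
    vol = Volume(
        data=np.zeros(spec.shape, dtype=np.int16),
        spacing=np.array(spec.spacing),
        origin=np.zeros(3),
        direction=np.eye(3),
    )
    px, py, pz = voxel_center_grid(vol)
    c = spec.center

    body = _ellipsoid(px, py, pz, c, spec.torso_half_axes)

    lung = np.zeros(spec.shape, dtype=bool)
    if spec.lung_half_axes is not None:
        for sx in (-1.0, 1.0):
            lc = c + np.array([sx * spec.lung_offset_x, 0.0, 0.0])
            lung |= _ellipsoid(px, py, pz, lc, spec.lung_half_axes)
        if np.any(lung & ~body):
            raise PhantomSpecError("lung cavities must lie strictly inside the torso")

    bone = np.zeros(spec.shape, dtype=bool)
    if spec.rib_count > 0:
        bone |= _rib_arcs(px, py, pz, c, spec)
    if spec.spine_radius > 0:
        spine_xy = (c[0], c[1] - 0.6 * spec.torso_half_axes[1])
        bone |= _cylinder_z(px, py, pz, spine_xy, spec.spine_radius, c[2], 0.9 * spec.torso_half_axes[2])

    arm = np.zeros(spec.shape, dtype=bool)
    if spec.arm_radius > 0 and spec.arm_offset is not None:
        axis = (c[0] + spec.arm_offset[0], c[1] + spec.arm_offset[1])
        arm = _cylinder_z(px, py, pz, axis, spec.arm_radius, c[2], spec.arm_half_length)
        if np.any(arm & body):
            raise PhantomSpecError("arm cylinder must be detached from the torso")

    nostril = np.zeros(spec.shape, dtype=bool)
    if spec.nostril_diameter > 0:
        # narrow air channel along +y from outside air into the torso interior
        nx = c[0] + spec.nostril_offset_x
        r = spec.nostril_diameter / 2.0
        in_tube = (px - nx) ** 2 + (pz - c[2]) ** 2 <= r**2
        nostril = in_tube & (py >= c[1] + 0.4 * spec.torso_half_axes[1])

    data = np.full(spec.shape, spec.hu_air, dtype=float)
    data[body] = spec.hu_soft
    data[arm] = spec.hu_soft
    data[nostril & body] = spec.hu_air  # carved channel
    data[lung] = spec.hu_lung
    data[bone & body] = spec.hu_bone
    vol.data = data

    structures = {
        "body": body,
        "lung": lung,
        "bone": bone & body,
        "arm": arm,
        "nostril": nostril & body,
        "body_with_arm": body | arm,
    }
    return PhantomData(volume=vol, body_mask=body, structures=structures, spec=spec)


# ---------------------------------------------------------------------------
# Named study phantoms (sphere, torso+lungs, nostril, rib cage, arm occluder)
# ---------------------------------------------------------------------------

def sphere_spec(n: int = 96, spacing: float = 2.0, radius: float = 60.0, **kw) -> PhantomSpec:
    return PhantomSpec(shape=(n, n, n), spacing=(spacing,) * 3, torso_half_axes=(radius,) * 3, **kw)


def torso_lung_spec(n: int = 96, spacing: float = 2.0, **kw) -> PhantomSpec:
    return PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3,
        torso_half_axes=(70.0, 55.0, 85.0), lung_half_axes=(24.0, 30.0, 48.0), **kw,
    )


def nostril_spec(n: int = 96, spacing: float = 2.0, diameter: float = 6.0, **kw) -> PhantomSpec:
    return PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3,
        torso_half_axes=(70.0, 55.0, 85.0), nostril_diameter=diameter, **kw,
    )


def rib_cage_spec(n: int = 96, spacing: float = 2.0, ribs: int = 6, **kw) -> PhantomSpec:
    return PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3,
        torso_half_axes=(70.0, 55.0, 85.0), rib_count=ribs, spine_radius=10.0, **kw,
    )


def arm_spec(n: int = 96, spacing: float = 2.0, **kw) -> PhantomSpec:
    return PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3,
        torso_half_axes=(55.0, 45.0, 70.0), arm_offset=(72.0, 0.0), arm_radius=14.0, **kw,
    )


def study_specs(n: int = 96, spacing: float = 2.0) -> dict[str, PhantomSpec]:
    """The five canonical phantoms used throughout validation."""
    return {
        "sphere": sphere_spec(n, spacing),
        "torso_lungs": torso_lung_spec(n, spacing),
        "nostril": nostril_spec(n, spacing),
        "rib_cage": rib_cage_spec(n, spacing),
        "arm": arm_spec(n, spacing),
    }


# ---------------------------------------------------------------------------
# Hand-eye calibration pose pairs
# ---------------------------------------------------------------------------

@dataclass
class PosePairSet:
    """Paired robot poses B_i = base->end-effector and tracker poses
    C_i = marker->camera, generated so that B_i X C_i = Y with ground truth
    X = end-effector->marker and Y = base->camera."""

    robot_poses: list[RigidTransform]
    tracker_poses: list[RigidTransform]
    x_true: RigidTransform | None = None  # unknown for recorded (non-synthetic) sets
    y_true: RigidTransform | None = None
    noise_t: float = 0.0
    noise_r: float = 0.0
    seed: int = 0

    def __len__(self) -> int:
        return len(self.robot_poses)


def _perturb(t: RigidTransform, rng: np.random.Generator, noise_t: float, noise_r: float) -> RigidTransform:
    if noise_t == 0 and noise_r == 0:
        return t
    angle = abs(rng.normal(0.0, np.radians(noise_r)))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    dr = Rotation.from_rotvec(angle * axis).as_matrix()
    dt = rng.normal(0.0, noise_t, size=3)
    return RigidTransform.from_rotation_translation(dr @ t.rotation, t.translation + dt)


def make_pose_pairs(
    n: int = 60,
    noise_t: float = 0.0,
    noise_r: float = 0.0,
    seed: int = 0,
    axis: np.ndarray | None = None,
) -> PosePairSet:
    """Generate hand-eye pose pairs with known ground truth.

    Robot poses have uniformly random orientations (spanning all axes) and
    translations inside a 600 mm workspace cube. Measurement noise is applied
    to the tracked poses: a random small rotation with angle ~ |N(0, noise_r)|
    degrees about a random axis, and translation noise N(0, noise_t) mm per
    component. ``axis`` restricts all robot rotations to a single axis, which
    is the classic degenerate configuration for hand-eye problems.
    """
    if n < 3:
        raise DegeneratePoseSetError("hand-eye calibration needs at least 3 pose pairs")
    rng = np.random.default_rng(seed)
    x_true = RigidTransform.random(rng, max_translation=120.0)
    y_true = RigidTransform.random(rng, max_translation=800.0)
    x_inv, y = x_true.inverse(), y_true
    robot, tracker = [], []
    for _ in range(n):
        if axis is None:
            rot = Rotation.random(random_state=rng).as_matrix()
        else:
            a = np.asarray(axis, dtype=float)
            a = a / np.linalg.norm(a)
            rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi) * a).as_matrix()
        b = RigidTransform.from_rotation_translation(rot, rng.uniform(-300.0, 300.0, size=3))
        c = x_inv @ b.inverse() @ y  # exact: B X C = Y
        robot.append(b)
        tracker.append(_perturb(c, rng, noise_t, noise_r))
    return PosePairSet(robot, tracker, x_true, y_true, noise_t, noise_r, seed)


# ---------------------------------------------------------------------------
# Fiducial registration phantom (steel-ball grid)
# ---------------------------------------------------------------------------

# Fixed in-plane jitter (mm) breaking the symmetry of the 4x6 grid so that
# pairwise-distance fingerprints identify every ball uniquely.
_JITTER = np.array([
    [1.9, -2.3], [-2.7, 0.8], [0.4, 2.9], [-1.2, -1.7], [2.8, 1.1], [-0.6, -2.9],
    [2.2, 2.4], [-2.9, -0.3], [0.9, -2.6], [1.5, 2.1], [-2.1, 1.6], [0.1, -0.9],
    [-1.8, 2.7], [2.5, -1.4], [-0.2, 1.3], [1.1, -2.1], [-2.4, -2.2], [2.9, 0.2],
    [0.6, 2.2], [-1.5, -0.6], [1.7, 1.8], [-2.6, 2.5], [0.2, -2.4], [2.3, -0.8],
])

# Irregular class pattern: True = 5 mm ball, False = 2 mm ball (12 each).
_LARGE = np.array([
    True, False, False, True, True, False, False, True, True, False, True, False,
    False, True, False, True, False, True, True, False, False, True, False, True,
])


@dataclass
class FiducialSet:
    """A steel-ball registration phantom with ground truth.

    ``cad_centers`` are the ball centers in the phantom's own (SB) frame;
    ``ct_from_sb`` is the ground-truth transform mapping SB into CT world
    coordinates; ``volume`` contains the rasterized balls.
    """

    cad_centers: np.ndarray  # (24, 3) mm, SB frame
    radii: np.ndarray  # (24,) mm
    ct_from_sb: RigidTransform
    volume: Volume
    seed: int

    @property
    def is_large(self) -> np.ndarray:
        return self.radii > 3.0


def fiducial_cad_grid() -> tuple[np.ndarray, np.ndarray]:
    """The phantom's CAD geometry: 24 jittered grid positions and radii."""
    ix, iy = np.meshgrid(np.arange(4), np.arange(6), indexing="ij")
    base = np.stack([ix.ravel() * 20.0, iy.ravel() * 18.0], axis=1)
    xy = base + _JITTER
    centers = np.column_stack([xy, np.zeros(24)])
    radii = np.where(_LARGE, 5.0, 2.0)
    return centers, radii


def make_fiducial_set(seed: int = 0, spacing: float = 0.6, margin: float = 8.0) -> FiducialSet:
    """Rasterize the steel-ball grid under a random rigid pose into a CT volume.

    The grid is sized to enclose every transformed ball plus ``margin`` mm, so
    all balls are fully inside the volume regardless of the pose.
    """
    rng = np.random.default_rng(seed)
    cad, radii = fiducial_cad_grid()
    ct_from_sb = RigidTransform.random(rng, max_translation=60.0)
    centers_ct = ct_from_sb.apply(cad)

    lo = centers_ct.min(axis=0) - (radii.max() + margin)
    hi = centers_ct.max(axis=0) + (radii.max() + margin)
    shape = tuple(int(np.ceil(e / spacing)) + 1 for e in hi - lo)
    vol = Volume(
        data=np.full(shape, -1000.0, dtype=float),
        spacing=np.full(3, spacing),
        origin=lo,
        direction=np.eye(3),
    )
    px, py, pz = voxel_center_grid(vol)
    for center, r in zip(centers_ct, radii):
        inside = (px - center[0]) ** 2 + (py - center[1]) ** 2 + (pz - center[2]) ** 2 <= r**2
        vol.data[inside] = 3000.0
    return FiducialSet(cad_centers=cad, radii=radii, ct_from_sb=ct_from_sb, volume=vol, seed=seed)
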
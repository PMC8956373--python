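"""Hand-eye calibration, fiducial registration, and the transform chain.

Hand-eye calibration solves for the end-effector->marker transform X and the
base->camera transform Y from n paired poses satisfying

    B_i  X  C_i = Y          (B_i: base->end-effector, C_i: marker->camera)

with the QR24 formulation: all 24 entries of (X, Y) — two 3x3 rotation
blocks plus two translations — are treated as free parameters of one stacked
linear least-squares system, solved without orthogonality constraints, and
each rotation block is then projected onto the nearest proper rotation.
Dropping the constraints is what makes the problem exactly linear; the
projection error is of the order of the pose noise.

CT-to-robot registration detects a grid of steel-ball fiducials in the scan,
matches them to the phantom's CAD coordinates via pairwise-distance
fingerprints (two ball radius classes break the grid's symmetry), fits a
rigid transform, and composes the chain

    base->CT = (base->camera) (camera->marker) (marker->balls) (balls->CT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .phantom import PosePairSet
from .transforms import RigidTransform, nearest_rotation


class CalibrationError(RuntimeError):
    """Degenerate or rank-deficient pose set."""


class FitError(ValueError):
    """Degenerate point configuration for rigid fitting."""


class MatchError(ValueError):
    """Fiducial correspondence failure (count mismatch or inconsistency)."""


class AmbiguityError(MatchError):
    """More than one fiducial correspondence fits within tolerance."""


@dataclass
class CalibrationResult:
    """Estimated hand-eye transforms with per-pose residuals."""

    x: RigidTransform  # end-effector -> marker
    y: RigidTransform  # base -> camera
    translation_errors: np.ndarray  # mm, per pose
    rotation_errors: np.ndarray  # deg, per pose
    condition: float

    @property
    def mean_t_err(self) -> float:
        return float(self.translation_errors.mean())

    @property
    def sd_t_err(self) -> float:
        return float(self.translation_errors.std(ddof=1)) if len(self.translation_errors) > 1 else 0.0

    @property
    def mean_r_err(self) -> float:
        return float(self.rotation_errors.mean())

    @property
    def sd_r_err(self) -> float:
        return float(self.rotation_errors.std(ddof=1)) if len(self.rotation_errors) > 1 else 0.0

    def report(self) -> dict[str, float]:
        return {
            "mean_t_err_mm": self.mean_t_err,
            "sd_t_err_mm": self.sd_t_err,
            "mean_r_err_deg": self.mean_r_err,
            "sd_r_err_deg": self.sd_r_err,
        }


def _check_rotation_diversity(rotations: list[np.ndarray], tol_deg: float = 0.5) -> None:
    """Hand-eye needs relative rotations about >= 2 independent axes."""
    axes = []
    r0 = rotations[0]
    for r in rotations[1:]:
        rel = Rotation.from_matrix(r0.T @ r)
        v = rel.as_rotvec()
        if np.linalg.norm(v) > np.radians(tol_deg):
            axes.append(v / np.linalg.norm(v))
    if not axes:
        raise CalibrationError("pose set has no relative rotation")
    a0 = axes[0]
    if all(np.linalg.norm(np.cross(a0, a)) < np.radians(tol_deg) for a in axes):
        raise CalibrationError("all relative rotations share one axis; hand-eye problem is degenerate")


def qr24_hand_eye(pairs: PosePairSet) -> CalibrationResult:
    """Solve B_i X C_i = Y for X, Y by unconstrained linear least squares.

    Unknowns are stacked as w = [vec(R_X); t_X; vec(R_Y); t_Y] (column-major
    vec, 24 entries). Per pose, the rotation block contributes
    (R_C^T kron R_B) vec(R_X) - vec(R_Y) = 0 and the translation block
    (t_C^T kron R_B) vec(R_X) + R_B t_X - t_Y = -t_B. Rotations are
    re-orthonormalized afterwards via the polar factor; residuals are
    reported after projection.
    """
    n = len(pairs)
    if n < 3:
        raise CalibrationError("need at least 3 pose pairs")
    _check_rotation_diversity([b.rotation for b in pairs.robot_poses])

    a_rows, b_rows = [], []
    for b, c in zip(pairs.robot_poses, pairs.tracker_poses):
        rb, tb = b.rotation, b.translation
        rc, tc = c.rotation, c.translation
        rot = np.zeros((9, 24))
        rot[:, :9] = np.kron(rc.T, rb)
        rot[:, 12:21] = -np.eye(9)
        a_rows.append(rot)
        b_rows.append(np.zeros(9))
        tr = np.zeros((3, 24))
        tr[:, :9] = np.kron(tc[None, :], rb)
        tr[:, 9:12] = rb
        tr[:, 21:24] = -np.eye(3)
        a_rows.append(tr)
        b_rows.append(-tb)
    a = np.vstack(a_rows)
    rhs = np.concatenate(b_rows)
    w, _, rank, sv = np.linalg.lstsq(a, rhs, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < 24:
        raise CalibrationError(f"linear system rank-deficient (rank {rank} < 24, cond {cond:.3g})")

    rx = nearest_rotation(w[:9].reshape(3, 3, order="F"))
    ry = nearest_rotation(w[12:21].reshape(3, 3, order="F"))
    x = RigidTransform.from_rotation_translation(rx, w[9:12])
    y = RigidTransform.from_rotation_translation(ry, w[21:24])

    t_err = np.empty(n)
    r_err = np.empty(n)
    for i, (b, c) in enumerate(zip(pairs.robot_poses, pairs.tracker_poses)):
        pred = b @ x @ c
        t_err[i] = pred.translation_distance_to(y)
        r_err[i] = pred.rotation_angle_to(y)
    return CalibrationResult(x=x, y=y, translation_errors=t_err, rotation_errors=r_err, condition=cond)


def rigid_fit(source: np.ndarray, destination: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform T minimizing sum ||T s_i - d_i||^2.

    Kabsch/Horn solution with proper-rotation (det +1) correction. Returns
    the transform and the post-fit RMSE in mm.
    """
    s = np.asarray(source, dtype=float)
    d = np.asarray(destination, dtype=float)
    if s.shape != d.shape or s.ndim != 2 or s.shape[1] != 3:
        raise FitError("source and destination must be matching (n, 3) arrays")
    if len(s) < 3:
        raise FitError("need at least 3 point pairs")
    sc, dc = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - sc, d - dc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise FitError("source points are collinear; rotation unobservable")
    rot = nearest_rotation(d0.T @ s0)
    t = dc - rot @ sc
    transform = RigidTransform.from_rotation_translation(rot, t)
    rmse = float(np.sqrt(np.mean(np.sum((transform.apply(s) - d) ** 2, axis=1))))
    return transform, rmse


def _fingerprints(points: np.ndarray, classes: np.ndarray) -> list[np.ndarray]:
    """Rigid-invariant descriptor per point: sorted distances to same-class
    points concatenated with sorted distances to other-class points."""
    out = []
    for i in range(len(points)):
        d = np.linalg.norm(points - points[i], axis=1)
        same = np.sort(d[(classes == classes[i]) & (np.arange(len(points)) != i)])
        other = np.sort(d[classes != classes[i]])
        out.append(np.concatenate([same, other]))
    return out


def _assignment_consistent(det_pts, cad_pts, det_idx, cad_idx, tol) -> bool:
    dd = np.linalg.norm(det_pts[det_idx][:, None] - det_pts[det_idx][None], axis=-1)
    dc = np.linalg.norm(cad_pts[cad_idx][:, None] - cad_pts[cad_idx][None], axis=-1)
    return bool(np.max(np.abs(dd - dc)) <= tol)


def match_fiducials(
    detected: list[tuple[np.ndarray, float]],
    cad: tuple[np.ndarray, np.ndarray],
    tol: float = 1.0,
) -> np.ndarray:
    """Correspond detected ball centroids to CAD ball centers.

    ``detected`` holds (centroid, volume_mm3) records; ``cad`` holds the
    (n, 3) CAD centers and the (n,) ball radii. Detected components are
    split into radius classes by volume (largest components -> large class),
    then matched within the class structure by pairwise-distance
    fingerprints, which are invariant to the unknown rigid pose. Returns
    ``corr`` with ``cad_center[corr[i]]`` matching ``detected[i]``.

    Raises :class:`MatchError` on count mismatch or geometric inconsistency
    beyond ``tol`` mm, and :class:`AmbiguityError` if a second, distinct
    bijection is also consistent within ``tol``.
    """
    cad_pts, radii = np.asarray(cad[0], dtype=float), np.asarray(cad[1], dtype=float)
    if len(detected) != len(cad_pts):
        raise MatchError(f"detected {len(detected)} components, expected {len(cad_pts)}")
    det_pts = np.array([c for c, _ in detected], dtype=float)
    volumes = np.array([v for _, v in detected])

    cad_large = radii > np.mean([radii.min(), radii.max()])
    n_large = int(cad_large.sum())
    det_large = np.zeros(len(detected), dtype=bool)
    det_large[np.argsort(volumes)[::-1][:n_large]] = True

    fp_det = _fingerprints(det_pts, det_large)
    fp_cad = _fingerprints(cad_pts, cad_large)

    corr = np.full(len(det_pts), -1, dtype=int)
    for is_large in (True, False):
        di = np.flatnonzero(det_large == is_large)
        ci = np.flatnonzero(cad_large == is_large)
        if di.size == 0:
            continue
        cost = np.array([[np.max(np.abs(fp_det[i] - fp_cad[j])) for j in ci] for i in di])
        rows, cols = linear_sum_assignment(cost)
        if np.any(cost[rows, cols] > tol):
            raise MatchError("no fiducial correspondence within tolerance")
        corr[di[rows]] = ci[cols]
        # ambiguity: forbid each matched pair in turn; if a full alternative
        # assignment also sits within tolerance, the grid is symmetric
        for r, c in zip(rows, cols):
            alt = cost.copy()
            alt[r, c] = np.inf
            ar, ac = linear_sum_assignment(alt)
            if np.isfinite(alt[ar, ac]).all() and np.all(alt[ar, ac] <= tol):
                raise AmbiguityError("two candidate fiducial correspondences within tolerance")

    if not _assignment_consistent(det_pts, cad_pts, np.arange(len(det_pts)), corr, tol):
        raise MatchError("matched pairwise distances disagree beyond tolerance")
    return corr


def compose_chain(transforms: list[RigidTransform]) -> RigidTransform:
    """Matrix product of an ordered transform list (leftmost applied last)."""
    if not transforms:
        raise ValueError("transform list must be non-empty")
    out = transforms[0]
    for t in transforms[1:]:
        out = out @ t
    return out


def needle_tip_offset(tip_in_ee: np.ndarray) -> RigidTransform:
    """The needle tip as a pure-translation link appended to the end-effector
    frame (e.g. (0, 0, 190) mm for the guide needle)."""
    tip = np.asarray(tip_in_ee, dtype=float)
    if not np.all(np.isfinite(tip)):
        raise ValueError("tip offset must be finite")
    return RigidTransform.from_translation(tip)


def register_ct_to_base(
    detected: list[tuple[np.ndarray, float]],
    cad: tuple[np.ndarray, np.ndarray],
    y_base_cam: RigidTransform,
    cam_from_marker: RigidTransform,
    marker_from_balls: RigidTransform,
    tol: float = 1.0,
) -> tuple[RigidTransform, float]:
    """Full CT registration: fiducial matching + rigid fit + chain composition.

    Returns base->CT and the fiducial-fit RMSE. ``cam_from_marker`` is the
    tracked pose of the registration phantom's reflective markers;
    ``marker_from_balls`` comes from the phantom CAD model.
    """
    corr = match_fiducials(detected, cad, tol=tol)
    det_pts = np.array([c for c, _ in detected])
    ct_from_balls, rmse = rigid_fit(np.asarray(cad[0])[corr], det_pts)
    base_from_ct = compose_chain([y_base_cam, cam_from_marker, marker_from_balls, ct_from_balls.inverse()])
    return base_from_ct, rmse
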
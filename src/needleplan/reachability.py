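"""Robot reachability of candidate entry points.

The planner only needs a predicate "can the robot realize this entry->target
insertion"; any kinematics engine satisfying that contract can be plugged in.
The default model shipped here is purely geometric: a reach annulus around
the robot base, a straight retracted approach corridor that must not collide
with the skin, and a forbidden half-space modeling the CT gantry.

To keep evaluation cheap, candidates are binned on a coarse planar grid
(30 x 30 mm by default) along the CT axes and the oracle is evaluated once
per occupied cell; the verdict is broadcast to all candidates in the cell.
Cells are independent, so evaluation parallelizes trivially.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import partial
from typing import Callable

import numpy as np

from .segmentation import SurfaceMesh


@dataclass
class ReachabilityConfig:
    """Geometric reachability model parameters (world mm)."""

    base: np.ndarray  # robot base position
    r_min: float = 300.0
    r_max: float = 820.0
    gantry_point: np.ndarray | None = None
    gantry_normal: np.ndarray | None = None  # forbidden side: normal . (x - point) > 0
    approach_clearance: float = 100.0
    grid_spacing: float = 30.0

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        if not 0 <= self.r_min <= self.r_max:
            raise ValueError("need 0 <= r_min <= r_max")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.gantry_normal is not None:
            n = np.asarray(self.gantry_normal, dtype=float)
            self.gantry_normal = n / np.linalg.norm(n)
            self.gantry_point = np.asarray(self.gantry_point, dtype=float)


def _in_forbidden_halfspace(cfg: ReachabilityConfig, points: np.ndarray) -> np.ndarray:
    if cfg.gantry_normal is None:
        return np.zeros(len(np.atleast_2d(points)), dtype=bool)
    p = np.atleast_2d(points)
    return (p - cfg.gantry_point) @ cfg.gantry_normal > 0


def _segment_hits_mesh(mesh: SurfaceMesh, origin: np.ndarray, direction: np.ndarray,
                       t_min: float, t_max: float) -> bool:
    """Moller-Trumbore ray/triangle test, vectorized over all faces, restricted
    to hit parameters in (t_min, t_max]."""
    tris = mesh.vertices[mesh.faces]
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    vv = q @ direction * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= 0) & (vv >= 0) & (u + vv <= 1) & (t > t_min) & (t <= t_max)
    return bool(hit.any())


def reachable(
    entry: np.ndarray,
    target: np.ndarray,
    cfg: ReachabilityConfig,
    mesh: SurfaceMesh | None = None,
) -> bool:
    """Default geometric reachability test for one entry->target insertion.

    True iff (i) the entry lies in the reach annulus [r_min, r_max] around
    the base, (ii) the retracted approach segment (entry out to
    ``approach_clearance`` mm along the insertion axis) stays clear of the
    skin mesh and of the gantry half-space, and (iii) the target itself is
    clear of the gantry half-space.
    """
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    r = np.linalg.norm(entry - cfg.base)
    if not cfg.r_min <= r <= cfg.r_max:
        return False
    u = entry - target
    u = u / np.linalg.norm(u)
    approach_end = entry + cfg.approach_clearance * u
    pts = np.vstack([entry, approach_end, target])
    if _in_forbidden_halfspace(cfg, pts[:2]).any():
        return False
    if _in_forbidden_halfspace(cfg, pts[2:]).any():
        return False
    if mesh is not None and cfg.approach_clearance > 0:
        # hits within 1 mm of the entry belong to the entry's own triangles
        if _segment_hits_mesh(mesh, entry, u, 1.0, cfg.approach_clearance):
            return False
    return True


def grid_reachability(
    mesh: SurfaceMesh,
    candidates: np.ndarray,
    target: np.ndarray,
    cfg: ReachabilityConfig,
    oracle: Callable[[np.ndarray, np.ndarray], bool] | None = None,
) -> tuple[np.ndarray, int]:
    """Evaluate reachability on a sparse planar grid.

    The grid is laid out as ``grid_spacing`` cells on the two CT axes spanning
    the largest face of the mesh bounding box; because a closed skin surface
    projects both its near and far side into the same planar cell, cells are
    additionally split along the remaining axis at the same spacing, keeping
    opposite sides of the body in separate cells. The oracle runs once per
    non-empty cell, at the candidate nearest the cell center, and the verdict
    is broadcast cell-wide. Returns the per-candidate booleans and the number
    of oracle calls (== number of non-empty cells).
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate set must be non-empty")
    if oracle is None:
        oracle = partial(reachable, cfg=cfg, mesh=mesh)
    target = np.asarray(target, dtype=float)
    pos = mesh.vertices[candidates]
    lo = mesh.vertices.min(axis=0)
    cells = np.floor((pos - lo) / cfg.grid_spacing).astype(int)
    out = np.zeros(candidates.size, dtype=bool)
    calls = 0
    # order-independent: each cell's verdict depends only on its own members
    _, keys = np.unique(cells, axis=0, return_inverse=True)
    for key in np.unique(keys):
        members = np.flatnonzero(keys == key)
        center = lo + (cells[members[0]] + 0.5) * cfg.grid_spacing
        dist2 = np.sum((pos[members] - center) ** 2, axis=1)
        probe = members[int(np.argmin(dist2))]
        verdict = bool(oracle(pos[probe], target))
        calls += 1
        out[members] = verdict
    return out, calls


def make_oracle(cfg: ReachabilityConfig):
    """Adapter matching the planner's reachability-oracle contract:
    (mesh, candidate_indices, target) -> bool array."""

    def _oracle(mesh: SurfaceMesh, candidates: np.ndarray, target: np.ndarray) -> np.ndarray:
        ok, _ = grid_reachability(mesh, candidates, target, cfg)
        return ok

    return _oracle
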
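"""Per-vertex insertion feasibility and cost: the skin heat map.

For an annotated target, every skin-mesh vertex is classified by walking the
planning steps in order — needle range, occlusion by other body parts, dense
tissue along the path (maximum HU projection), safety margin around dense
regions, insertion angle, robot reachability — and every surviving vertex is
scored with the cost

    q = 0.5 * (d / l) + 0.5 * (a / 90)

where d is the insertion depth (mm), l the effective needle length (mm) and a
the angle (deg) between the needle direction and the inward skin normal. The
entry with minimal q is the suggested insertion point: the score trades short
paths against perpendicular skin entry, both of which favor placement
accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .segmentation import BodyMask, SurfaceMesh
from .volume_io import Volume


class Category(IntEnum):
    """Vertex classification, in precedence order (lowest wins)."""

    OUT_OF_RANGE = 0  # farther from the target than the needle length
    OCCLUDED = 1      # another body part blocks the air path to the skin
    DENSE_BLOCKED = 2  # bone / implant on the needle path
    MARGIN_BLOCKED = 3  # within the safety margin of a dense-blocked vertex
    ANGLE_BLOCKED = 4  # grazing insertion (angle >= max_angle)
    UNREACHABLE = 5   # rejected by the robot reachability oracle
    FEASIBLE = 6


class OutOfBoundsError(ValueError):
    """Raised when a ray segment leaves the volume extent."""


class TargetOutsideBodyError(ValueError):
    pass


class NoPathError(RuntimeError):
    """No feasible insertion point exists for this target."""


class DomainError(ValueError):
    pass


@dataclass
class PathConstraints:
    """Planning constraints. Defaults reflect a 190 mm guide needle with an
    effective insertion length of 160 mm and a 5 mm bone safety margin."""

    needle_length: float = 160.0
    dense_hu_threshold: float = 300.0
    margin: float = 5.0
    max_angle: float = 90.0
    clearance: float = 190.0
    ray_step: float | None = None  # default: min(spacing) / 2

    def __post_init__(self) -> None:
        if self.needle_length <= 0:
            raise ValueError("needle_length must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if not 0 < self.max_angle <= 90:
            raise ValueError("max_angle must be in (0, 90]")


# reachability oracle contract: (mesh, candidate_indices, target) -> bool array
ReachOracle = Callable[[SurfaceMesh, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class SurfaceMap:
    """Per-vertex feasibility categories and scalars for one target.

    Scalars are NaN where not computed (depth everywhere; angle, max_hu for
    all in-range vertices; cost only where FEASIBLE).
    """

    mesh: SurfaceMesh
    target: np.ndarray
    category: np.ndarray  # (n,) Category codes
    depth: np.ndarray  # (n,) mm
    angle: np.ndarray  # (n,) deg
    max_hu: np.ndarray  # (n,) HU
    cost: np.ndarray  # (n,) in [0, 1] where FEASIBLE
    constraints: PathConstraints = field(default_factory=PathConstraints)

    @property
    def feasible(self) -> np.ndarray:
        return self.category == Category.FEASIBLE

    def counts(self) -> dict[str, int]:
        return {c.name: int(np.sum(self.category == c)) for c in Category}


@dataclass
class InsertionPlan:
    """The selected insertion: entry vertex, depth, angle and cost."""

    target: np.ndarray
    entry: np.ndarray
    vertex: int
    depth: float
    angle: float
    cost: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "target_mm": list(map(float, self.target)),
                "entry_mm": list(map(float, self.entry)),
                "vertex": int(self.vertex),
                "depth_mm": self.depth,
                "angle_deg": self.angle,
                "cost": self.cost,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _segment_samples(target: np.ndarray, entries: np.ndarray, step: float) -> np.ndarray:
    """Sample points (m, k, 3) from target to each entry, spacing <= step."""
    entries = np.atleast_2d(entries)
    d = np.linalg.norm(entries - target, axis=1)
    k = max(2, int(np.ceil(d.max() / step)) + 1)
    t = np.linspace(0.0, 1.0, k)
    return target + t[None, :, None] * (entries - target)[:, None, :]


def _checked_idx(v: Volume, points: np.ndarray) -> np.ndarray:
    idx = v.world_to_voxel(points.reshape(-1, 3))
    lo_ok = np.all(idx >= -1e-9, axis=1)
    hi_ok = np.all(idx <= np.array(v.shape) - 1 + 1e-9, axis=1)
    if not np.all(lo_ok & hi_ok):
        raise OutOfBoundsError("ray segment exits the volume extent")
    return idx


def _interp_hu(v: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear HU at world points of arbitrary leading shape."""
    shape = points.shape[:-1]
    idx = _checked_idx(v, points)
    vals = map_coordinates(v.data.astype(float), idx.T, order=1, mode="nearest")
    return vals.reshape(shape)


def _corner_bound_field(v: Volume) -> np.ndarray:
    """5x5x5 maximum filter of the volume: an upper bound for the trilinear
    field anywhere within two voxels of each voxel center (enough to cover a
    whole coarse-sampling interval plus the interpolation cell). Cached per
    volume."""
    cached = getattr(v, "_corner_bound", None)
    if cached is None:
        from scipy.ndimage import maximum_filter

        cached = maximum_filter(v.data.astype(float), size=5, mode="nearest")
        v._corner_bound = cached  # type: ignore[attr-defined]
    return cached


def _ray_max_batch(v: Volume, target: np.ndarray, entries: np.ndarray, step: float) -> np.ndarray:
    """Max interpolated HU per ray, exact to fine-sampling resolution.

    A coarse pass samples the trilinear field at ``step``. Narrow peaks — a
    ray clipping the corner of a high-HU voxel cell — can hide entirely
    between coarse samples, so each coarse sample also reads a 3^3
    maximum-filtered copy of the volume, which bounds the trilinear field
    over the whole neighboring interval. Only the intervals where that bound
    exceeds the ray's running maximum are resampled 20x finer; the bound
    guarantees no peak is overlooked, and the refinement cost stays
    proportional to the dense-structure crossings.
    """
    entries = np.atleast_2d(entries)
    d = np.linalg.norm(entries - target, axis=1)
    k = max(3, int(np.ceil(d.max() / step)) + 1)
    t = np.linspace(0.0, 1.0, k)
    pts = target + t[None, :, None] * (entries - target)[:, None, :]
    idx = _checked_idx(v, pts)
    vals = map_coordinates(v.data.astype(float), idx.T, order=1, mode="nearest").reshape(len(entries), k)
    bound = map_coordinates(_corner_bound_field(v), idx.T, order=0, mode="nearest").reshape(len(entries), k)
    best = vals.max(axis=1)

    rows, cols = np.nonzero(bound > best[:, None] + 1e-9)
    if rows.size:
        fine_frac = np.linspace(0.0, 1.0, 21)
        chunk = max(1, 500_000 // 21)
        for s in range(0, rows.size, chunk):
            r, c = rows[s:s + chunk], cols[s:s + chunk]
            t_lo = t[np.clip(c - 1, 0, k - 1)]
            t_hi = t[np.clip(c + 1, 0, k - 1)]
            tf = t_lo[:, None] + fine_frac * (t_hi - t_lo)[:, None]  # (c, 21)
            fine_pts = target + tf[..., None] * (entries[r] - target)[:, None, :]
            fine = _interp_hu(v, fine_pts).max(axis=1)
            np.maximum.at(best, r, fine)
    return best


def ray_max_hu(v: Volume, target: np.ndarray, entry: np.ndarray, step: float | None = None,
               tol_mm: float = 0.002) -> float:
    """Maximum trilinearly interpolated HU along the target->entry segment.

    A coarse pass samples at ``step`` (at most ``step`` mm apart, endpoints
    included); intervals that may hide a higher value — judged by a
    maximum-filter upper bound of the field — are then subdivided
    branch-and-bound style until the surviving intervals are shorter than
    ``tol_mm``. The result is the true maximum of the interpolated profile
    to within the local slope times ``tol_mm``, independent of how narrowly
    a ray grazes a dense structure.
    """
    if step is None:
        step = float(np.min(v.spacing)) / 2.0
    if step <= 0:
        raise ValueError("step must be positive")
    target = np.asarray(target, float)
    entry = np.asarray(entry, float)
    d = float(np.linalg.norm(entry - target))
    k = max(3, int(np.ceil(d / step)) + 1)
    t = np.linspace(0.0, 1.0, k)
    pts = target + t[:, None] * (entry - target)
    idx = _checked_idx(v, pts)
    data = v.data.astype(float)
    vals = map_coordinates(data, idx.T, order=1, mode="nearest")
    bound_field = _corner_bound_field(v)
    bounds = map_coordinates(bound_field, idx.T, order=0, mode="nearest")
    best = float(vals.max())

    flagged = np.flatnonzero(bounds > best + 1e-9)
    if flagged.size == 0 or d == 0:
        return best
    lo = t[np.clip(flagged - 1, 0, k - 1)]
    hi = t[np.clip(flagged + 1, 0, k - 1)]
    tol_t = tol_mm / d
    while lo.size:
        mid = 0.5 * (lo + hi)
        pm = target + mid[:, None] * (entry - target)
        im = v.world_to_voxel(pm)
        best = max(best, float(map_coordinates(data, im.T, order=1, mode="nearest").max()))
        if np.all(hi - lo <= 2 * tol_t):
            break
        b = map_coordinates(bound_field, im.T, order=0, mode="nearest")
        keep = (b > best + 1e-9) & (hi - lo > 2 * tol_t)
        lo, hi, mid = lo[keep], hi[keep], mid[keep]
        lo = np.concatenate([lo, mid])
        hi = np.concatenate([mid, hi])
    return best


def occlusion_check(
    m: BodyMask,
    target: np.ndarray,
    entry: np.ndarray,
    clearance: float,
    step: float | None = None,
) -> bool:
    """True iff body tissue lies on the outward ray extension beyond the entry.

    The extension continues the target->entry direction for ``clearance`` mm
    past the entry; a detached arm across that corridor blocks the approach.
    Sampling starts two voxels past the entry: the mesh vertex lies on the
    smoothed isosurface, which can sit up to a voxel inside the interpolated
    binary boundary, and the guard keeps the body's own surface shell from
    reading as an obstacle.
    """
    occ = _occlusion_batch(m, np.asarray(target, float), np.atleast_2d(np.asarray(entry, float)), clearance, step)
    return bool(occ[0])


def _occlusion_batch(
    m: BodyMask, target: np.ndarray, entries: np.ndarray, clearance: float, step: float | None = None
) -> np.ndarray:
    if clearance <= 0:
        return np.zeros(len(entries), dtype=bool)
    if step is None:
        step = float(np.min(m.spacing)) / 2.0
    skip = 2.0 * float(np.max(m.spacing))  # surface-shell discretization guard
    if clearance <= skip:
        return np.zeros(len(entries), dtype=bool)
    u = entries - target
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    k = max(2, int(np.ceil((clearance - skip) / step)) + 1)
    offs = np.linspace(skip, clearance, k)
    pts = entries[:, None, :] + offs[None, :, None] * u[:, None, :]
    idx = m.world_to_voxel(pts.reshape(-1, 3))
    vals = map_coordinates(m.mask.astype(float), idx.T, order=1, mode="constant", cval=0.0)
    return (vals.reshape(len(entries), -1) > 0.5).any(axis=1)


def insertion_angle(mesh: SurfaceMesh, vertex: int, target: np.ndarray) -> float:
    """Angle (deg) between the insertion direction and the inward skin normal."""
    return float(_angles(mesh, np.array([vertex]), np.asarray(target, float))[0])


def _angles(mesh: SurfaceMesh, vertices: np.ndarray, target: np.ndarray) -> np.ndarray:
    pos = mesh.vertices[vertices]
    d = target - pos
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("target coincides with a vertex; insertion direction undefined")
    u = d / norms[:, None]
    inward = -mesh.vertex_normals[vertices]
    cosang = np.clip(np.einsum("ij,ij->i", u, inward), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def cost(d: float | np.ndarray, a: float | np.ndarray, l: float = 160.0) -> float | np.ndarray:
    """Insertion cost q = 0.5 d/l + 0.5 a/90, in [0, 1].

    Both terms carry a common positive normalization constant t which only
    rescales q and cannot change the ranking; it is fixed to 1 here.
    """
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(d < 0) or np.any(d > l):
        raise DomainError(f"depth must lie in [0, {l}] mm")
    if np.any(a < 0) or np.any(a > 90):
        raise DomainError("angle must lie in [0, 90] deg")
    q = 0.5 * (d / l) + 0.5 * (a / 90.0)
    return float(q) if q.ndim == 0 else q


def apply_margin(mesh: SurfaceMesh, blocked: np.ndarray, margin: float) -> np.ndarray:
    """Expand a blocked vertex set by a Euclidean safety margin.

    Returns the indices of all vertices within ``margin`` mm of any blocked
    vertex (including the blocked set itself). Metric distance on the mesh
    vertices makes the margin independent of mesh resolution.
    """
    blocked = np.asarray(blocked, dtype=int)
    if blocked.size == 0 or margin < 0:
        return blocked
    if margin == 0:
        return blocked
    tree = cKDTree(mesh.vertices[blocked])
    dist, _ = tree.query(mesh.vertices, k=1, distance_upper_bound=margin + 1e-12)
    return np.flatnonzero(np.isfinite(dist) & (dist <= margin))


# ---------------------------------------------------------------------------
# Map construction and queries
# ---------------------------------------------------------------------------

def build_surface_map(
    v: Volume,
    mesh: SurfaceMesh,
    target: np.ndarray,
    constraints: PathConstraints,
    body_mask: BodyMask,
    reach: ReachOracle | None = None,
) -> SurfaceMap:
    """Classify every skin vertex for an insertion to ``target``.

    Categories are assigned with precedence OUT_OF_RANGE -> OCCLUDED ->
    DENSE_BLOCKED -> MARGIN_BLOCKED -> ANGLE_BLOCKED -> UNREACHABLE ->
    FEASIBLE, mirroring the order of the planning steps. An empty feasible
    set is a valid (warning-state) output; only a target outside the body is
    an error.
    """
    target = np.asarray(target, dtype=float)
    if not body_mask.contains(target):
        raise TargetOutsideBodyError("target must lie strictly inside the body")
    c = constraints
    step = c.ray_step if c.ray_step is not None else float(np.min(v.spacing)) / 2.0
    n = len(mesh)
    cat = np.full(n, Category.FEASIBLE, dtype=int)
    depth = np.linalg.norm(mesh.vertices - target, axis=1)
    angle = np.full(n, np.nan)
    max_hu = np.full(n, np.nan)
    q = np.full(n, np.nan)

    in_range = depth < c.needle_length
    cat[~in_range] = Category.OUT_OF_RANGE
    idx = np.flatnonzero(in_range)
    if idx.size:
        angle[idx] = _angles(mesh, idx, target)
        max_hu[idx] = _ray_max_batch(v, target, mesh.vertices[idx], step)

        occluded = _occlusion_batch(body_mask, target, mesh.vertices[idx], c.clearance, step)
        cat[idx[occluded]] = Category.OCCLUDED

        dense = (max_hu[idx] >= c.dense_hu_threshold) & ~occluded
        dense_idx = idx[dense]
        cat[dense_idx] = Category.DENSE_BLOCKED

        expanded = apply_margin(mesh, dense_idx, c.margin)
        margin_only = np.setdiff1d(expanded, dense_idx, assume_unique=False)
        margin_only = margin_only[cat[margin_only] == Category.FEASIBLE]
        cat[margin_only] = Category.MARGIN_BLOCKED

        open_idx = idx[cat[idx] == Category.FEASIBLE]
        bad_angle = angle[open_idx] >= c.max_angle
        cat[open_idx[bad_angle]] = Category.ANGLE_BLOCKED

        if reach is not None:
            cand = idx[cat[idx] == Category.FEASIBLE]
            if cand.size:
                ok = np.asarray(reach(mesh, cand, target), dtype=bool)
                cat[cand[~ok]] = Category.UNREACHABLE

        feas = np.flatnonzero(cat == Category.FEASIBLE)
        if feas.size:
            q[feas] = cost(depth[feas], angle[feas], c.needle_length)

    return SurfaceMap(mesh=mesh, target=target, category=cat, depth=depth,
                      angle=angle, max_hu=max_hu, cost=q, constraints=c)


def select_optimal(smap: SurfaceMap) -> InsertionPlan:
    """The feasible vertex with minimal cost; ties broken by smaller depth,
    then smallest vertex index."""
    feas = np.flatnonzero(smap.feasible)
    if feas.size == 0:
        raise NoPathError("no feasible insertion point for this target")
    order = np.lexsort((feas, smap.depth[feas], smap.cost[feas]))
    best = int(feas[order[0]])
    return InsertionPlan(
        target=smap.target,
        entry=smap.mesh.vertices[best].copy(),
        vertex=best,
        depth=float(smap.depth[best]),
        angle=float(smap.angle[best]),
        cost=float(smap.cost[best]),
    )


def feasible_area(mesh: SurfaceMesh, smap: SurfaceMap, mode: str = "robot") -> float:
    """Total area (mm^2) of triangles whose three vertices are insertable.

    ``mode="robot"`` counts FEASIBLE vertices only; ``mode="manual"`` ignores
    the reachability verdict (FEASIBLE or UNREACHABLE), i.e. the area where a
    needle could be inserted by hand.
    """
    if mode == "robot":
        ok = smap.category == Category.FEASIBLE
    elif mode == "manual":
        ok = (smap.category == Category.FEASIBLE) | (smap.category == Category.UNREACHABLE)
    else:
        raise ValueError("mode must be 'robot' or 'manual'")
    tri_ok = ok[mesh.faces].all(axis=1)
    return float(mesh.tri.area_faces[tri_ok].sum())


def relative_objective_distribution(smap: SurfaceMap, near_optimal: float = 0.1) -> tuple[np.ndarray, float]:
    """Cost normalized between the extrema over feasible vertices.

    Returns the per-feasible-vertex normalized cost and the fraction of
    vertices within ``near_optimal`` of the optimum — how forgiving a manual
    relocation of the suggested entry would be.
    """
    qs = smap.cost[smap.feasible]
    if qs.size < 2:
        raise ValueError("need at least 2 feasible vertices")
    lo, hi = qs.min(), qs.max()
    if hi - lo == 0:
        raise ValueError("all feasible costs equal; normalization undefined")
    rel = (qs - lo) / (hi - lo)
    return rel, float(np.mean(rel <= near_optimal))


# ---------------------------------------------------------------------------
# Export (heat-map meshes with per-vertex scalars)
# ---------------------------------------------------------------------------

_SCALARS = ("category", "depth", "angle", "max_hu", "cost")


def save_surface_map_vtk(smap: SurfaceMap, path: str | Path) -> None:
    """Write the mesh with all per-vertex scalar arrays as legacy VTK polydata
    (ASCII), renderable in ParaView / 3D Slicer."""
    mesh = smap.mesh
    lines = [
        "# vtk DataFile Version 3.0",
        "needleplan surface map",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} float",
    ]
    lines += [" ".join(f"{x:.6f}" for x in v) for v in mesh.vertices]
    nf = len(mesh.faces)
    lines.append(f"POLYGONS {nf} {4 * nf}")
    lines += ["3 " + " ".join(map(str, f)) for f in mesh.faces]
    lines.append(f"POINT_DATA {len(mesh.vertices)}")
    for name in _SCALARS:
        arr = getattr(smap, name)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{x:.6f}" if np.isfinite(x) else "-1" for x in np.asarray(arr, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def save_surface_map_ply(smap: SurfaceMap, path: str | Path, color_by: str = "cost", cmap: str = "viridis") -> None:
    """Write the mesh as PLY with vertices colored by one scalar overlay.

    Non-finite values (blocked vertices) are rendered grey; the rest follow
    the matplotlib colormap between the scalar's finite extrema.
    """
    import matplotlib
    import matplotlib.colors as mcolors

    if color_by not in _SCALARS:
        raise ValueError(f"color_by must be one of {_SCALARS}")
    vals = np.asarray(getattr(smap, color_by), dtype=float)
    finite = np.isfinite(vals)
    colors = np.full((len(vals), 4), [128, 128, 128, 255], dtype=np.uint8)
    if finite.any():
        norm = mcolors.Normalize(vmin=vals[finite].min(), vmax=vals[finite].max())
        rgba = matplotlib.colormaps[cmap](norm(vals[finite]))
        colors[finite] = (rgba * 255).astype(np.uint8)
    tri = smap.mesh.tri.copy()
    tri.visual.vertex_colors = colors
    tri.export(str(path))
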
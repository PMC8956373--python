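import numpy as np
import pytest
from scipy.spatial import cKDTree

from needleplan import (
    Category,
    PathConstraints,
    apply_margin,
    build_surface_map,
    cost,
    feasible_area,
    insertion_angle,
    occlusion_check,
    ray_max_hu,
    relative_objective_distribution,
    select_optimal,
)
from needleplan.pathmap import DomainError, NoPathError, OutOfBoundsError, TargetOutsideBodyError
from needleplan.volume_io import Volume


class TestRayMaxHu:
    def test_constant_field(self):
        v = Volume(np.full((20, 20, 20), 40.0), spacing=(1, 1, 1))
        assert ray_max_hu(v, [2, 2, 2], [15, 12, 9]) == pytest.approx(40.0)

    def test_bone_crossing(self, rib_case):
        ph, _, _ = rib_case
        spec = ph.spec
        c = spec.center
        z_arc = c[2] - 0.5 * (spec.rib_count - 1) * spec.rib_z_pitch
        target = np.array([c[0], c[1], z_arc])
        entry = np.array([c[0], c[1] + spec.torso_half_axes[1] + 5.0, z_arc])
        hu = ray_max_hu(ph.volume, target, entry, step=min(spec.spacing) / 4)
        assert abs(hu - spec.hu_bone) <= 1.0

    def test_agrees_with_finely_oversampled_oracle(self, rib_case, rng):
        # the reference samples 10x finer than the adaptive refinement
        # tolerance, so it bounds the implementation's remaining error
        ph, _, _ = rib_case
        v = ph.volume
        from scipy.interpolate import RegularGridInterpolator

        axes = [np.arange(n) for n in v.shape]
        interp = RegularGridInterpolator(axes, v.data.astype(float))
        step = min(v.spacing) / 2
        tol_mm = 0.002
        c = ph.spec.center
        for _ in range(20):
            a = c + rng.uniform(-1, 1, 3) * 20
            b = c + rng.uniform(-1, 1, 3) * np.array(ph.spec.torso_half_axes)
            d = np.linalg.norm(b - a)
            k = max(2, int(np.ceil(d / (tol_mm / 10))) + 1)
            pts = a + np.linspace(0, 1, k)[:, None] * (b - a)
            oracle = interp(v.world_to_voxel(pts)).max()
            assert abs(ray_max_hu(v, a, b, step, tol_mm=tol_mm) - oracle) <= 0.5

    def test_never_below_coarse_oracle(self, rib_case, rng):
        # a 10x oversampling of the base step can miss narrow grazing peaks;
        # the adaptive result must dominate whatever it finds
        ph, _, _ = rib_case
        v = ph.volume
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator([np.arange(n) for n in v.shape], v.data.astype(float))
        step = min(v.spacing) / 2
        c = ph.spec.center
        for _ in range(30):
            a = c + rng.uniform(-1, 1, 3) * 20
            b = c + rng.uniform(-1, 1, 3) * np.array(ph.spec.torso_half_axes)
            d = np.linalg.norm(b - a)
            k = max(2, int(np.ceil(d / (step / 10))) + 1)
            pts = a + np.linspace(0, 1, k)[:, None] * (b - a)
            oracle = interp(v.world_to_voxel(pts)).max()
            assert ray_max_hu(v, a, b, step) >= oracle - 1e-9

    def test_segment_outside_volume_rejected(self):
        v = Volume(np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(OutOfBoundsError):
            ray_max_hu(v, [5, 5, 5], [50, 5, 5])


class TestOcclusion:
    def test_convex_body_never_occluded(self, sphere_case):
        ph, mask, mesh = sphere_case
        target = ph.spec.center
        sub = mesh.vertices[::40]
        assert not any(occlusion_check(mask, target, e, clearance=190.0) for e in sub)

    def test_detached_arm_occludes_facing_vertices(self, arm_case):
        ph, _, mesh, full = arm_case
        c = ph.spec.center
        target = c.copy()
        # vertex on the +x side (towards the arm at offset (72, 0)) vs -x side
        i_face = int(np.argmax(mesh.vertices[:, 0]))
        i_away = int(np.argmin(mesh.vertices[:, 0]))
        assert occlusion_check(full, target, mesh.vertices[i_face], clearance=190.0)
        assert not occlusion_check(full, target, mesh.vertices[i_away], clearance=190.0)

    def test_zero_clearance_never_occludes(self, arm_case):
        ph, _, mesh, full = arm_case
        i_face = int(np.argmax(mesh.vertices[:, 0]))
        assert not occlusion_check(full, ph.spec.center, mesh.vertices[i_face], clearance=0.0)


class TestInsertionAngle:
    def test_along_inward_normal_is_zero(self, sphere_case):
        _, _, mesh = sphere_case
        target = mesh.vertices[0] - 30.0 * mesh.vertex_normals[0]
        # arccos loses half the floating-point digits near cos = 1
        assert insertion_angle(mesh, 0, target) < 1e-5

    def test_tangent_direction_is_ninety(self, sphere_case):
        _, _, mesh = sphere_case
        n = mesh.vertex_normals[0]
        t = np.cross(n, [0.0, 0.0, 1.0])
        t /= np.linalg.norm(t)
        target = mesh.vertices[0] + 25.0 * t
        assert abs(insertion_angle(mesh, 0, target) - 90.0) < 1e-9

    def test_sphere_center_nearly_zero_everywhere(self, sphere_case):
        ph, _, mesh = sphere_case
        angles = [insertion_angle(mesh, i, ph.spec.center) for i in range(0, len(mesh), 25)]
        assert max(angles) < 5.0  # limited only by mesh-normal discretization


class TestCost:
    def test_extremes_and_midpoint(self):
        assert cost(0.0, 0.0, 160.0) == 0.0
        assert cost(160.0, 90.0, 160.0) == 1.0
        assert cost(80.0, 45.0, 160.0) == 0.5

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            cost(-1.0, 10.0, 160.0)
        with pytest.raises(DomainError):
            cost(10.0, 95.0, 160.0)
        with pytest.raises(DomainError):
            cost(200.0, 10.0, 160.0)


class TestApplyMargin:
    def test_empty_and_zero_margin_identity(self, sphere_case):
        _, _, mesh = sphere_case
        assert apply_margin(mesh, np.array([], dtype=int), 5.0).size == 0
        blocked = np.array([3, 7])
        assert np.array_equal(apply_margin(mesh, blocked, 0.0), blocked)

    def test_exact_euclidean_ball(self, sphere_case):
        _, _, mesh = sphere_case
        blocked = np.array([10])
        expanded = apply_margin(mesh, blocked, 7.0)
        d = np.linalg.norm(mesh.vertices - mesh.vertices[10], axis=1)
        assert np.array_equal(np.sort(expanded), np.flatnonzero(d <= 7.0))


class TestBuildSurfaceMap:
    def test_unconstrained_sphere_all_feasible(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        assert np.all(smap.category == Category.FEASIBLE)
        assert np.all((smap.cost >= 0) & (smap.cost <= 1))

    def test_short_needle_all_out_of_range(self, sphere_case):
        ph, mask, mesh = sphere_case
        c = PathConstraints(needle_length=30.0)  # sphere radius is 60
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, c, mask)
        assert np.all(smap.category == Category.OUT_OF_RANGE)
        with pytest.raises(NoPathError):
            select_optimal(smap)

    def test_rib_shield_geometry(self, rib_case):
        ph, mask, mesh = rib_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        counts = smap.counts()
        assert counts["DENSE_BLOCKED"] > 0
        assert counts["MARGIN_BLOCKED"] > 0
        assert counts["FEASIBLE"] > 0
        dense = np.flatnonzero(smap.category == Category.DENSE_BLOCKED)
        marginal = np.flatnonzero(smap.category == Category.MARGIN_BLOCKED)
        dmin = cKDTree(mesh.vertices[dense]).query(mesh.vertices[marginal])[0]
        assert dmin.max() <= 5.0 + 1e-9  # margin vertices within 5 mm of a dense one
        feas = np.flatnonzero(smap.feasible)
        dfeas = cKDTree(mesh.vertices[dense]).query(mesh.vertices[feas])[0]
        assert dfeas.min() > 5.0

    def test_category_partition(self, rib_case):
        ph, mask, mesh = rib_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        assert sum(smap.counts().values()) == len(mesh)

    def test_target_outside_body_rejected(self, sphere_case):
        ph, mask, mesh = sphere_case
        outside = ph.spec.center + np.array([0.0, 0.0, 90.0])
        with pytest.raises(TargetOutsideBodyError):
            build_surface_map(ph.volume, mesh, outside, PathConstraints(), mask)

    def test_monotonicity_under_tightened_constraints(self, rib_case):
        ph, mask, mesh = rib_case
        base = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask).feasible
        for tight in (
            PathConstraints(needle_length=90.0),
            PathConstraints(margin=12.0),
            PathConstraints(dense_hu_threshold=0.0),
            PathConstraints(max_angle=45.0),
        ):
            feas = build_surface_map(ph.volume, mesh, ph.spec.center, tight, mask).feasible
            assert not np.any(feas & ~base)  # tightening never grows the feasible set


class TestSelectOptimal:
    def test_matches_exhaustive_argmin(self, rib_case):
        ph, mask, mesh = rib_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        plan = select_optimal(smap)
        feas = np.flatnonzero(smap.feasible)
        brute = feas[np.argmin(smap.cost[feas])]
        assert np.isclose(smap.cost[brute], plan.cost)
        assert plan.cost <= smap.cost[feas].min() + 1e-12
        assert np.isclose(plan.depth, np.linalg.norm(plan.entry - smap.target), atol=1e-9)

    def test_positive_scaling_preserves_argmin(self, torso_case):
        ph, mask, mesh = torso_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        plan = select_optimal(smap)
        for t in (0.25, 3.0):
            scaled = np.where(smap.feasible, smap.cost * t, np.nan)
            feas = np.flatnonzero(smap.feasible)
            assert feas[np.argmin(scaled[feas])] == plan.vertex

    def test_tie_breaks_by_depth_then_index(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        smap.cost[:] = np.where(smap.feasible, 0.5, np.nan)  # force a global cost tie
        plan = select_optimal(smap)
        feas = np.flatnonzero(smap.feasible)
        dmin = smap.depth[feas].min()
        assert plan.depth == dmin  # cost tie resolved by smaller depth
        smap.depth[:] = 42.0  # now also tie the depths
        plan = select_optimal(smap)
        assert plan.vertex == feas.min()  # final tie resolved by vertex index


class TestAreaAndDistribution:
    def test_full_surface_area(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        assert np.isclose(feasible_area(mesh, smap), mesh.area)

    def test_no_feasible_zero_area(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(needle_length=30.0), mask)
        assert feasible_area(mesh, smap) == 0.0

    def test_blocked_hemisphere_area(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        upper = mesh.vertices[:, 2] >= ph.spec.center[2]
        smap.category[~upper] = Category.DENSE_BLOCKED
        area = feasible_area(mesh, smap)
        r = ph.spec.torso_half_axes[0]
        assert abs(area - 2 * np.pi * r**2) / (2 * np.pi * r**2) < 0.05

    def test_manual_variant_includes_unreachable(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        smap.category[mesh.vertices[:, 0] > ph.spec.center[0]] = Category.UNREACHABLE
        assert feasible_area(mesh, smap, mode="manual") > feasible_area(mesh, smap, mode="robot")
        assert np.isclose(feasible_area(mesh, smap, mode="manual"), mesh.area)

    def test_relative_objective(self, torso_case):
        ph, mask, mesh = torso_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        rel, frac = relative_objective_distribution(smap)
        assert rel.min() == 0.0 and rel.max() == 1.0
        assert np.isclose(frac, np.mean(rel <= 0.1))

    def test_relative_objective_uniform_grid(self):
        # synthetic map with a uniform cost grid over [0, 1]
        from needleplan.pathmap import SurfaceMap
        from needleplan.segmentation import SurfaceMesh

        n = 1001
        verts = np.zeros((n, 3))
        mesh = SurfaceMesh(verts, np.zeros((1, 3), dtype=int), np.tile([0.0, 0.0, 1.0], (n, 1)))
        q = np.linspace(0, 1, n)
        smap = SurfaceMap(mesh, np.zeros(3), np.full(n, int(Category.FEASIBLE)), np.zeros(n),
                          np.zeros(n), np.zeros(n), q)
        _, frac = relative_objective_distribution(smap)
        assert abs(frac - 0.1) < 0.005

    def test_all_costs_equal_rejected(self, sphere_case):
        ph, mask, mesh = sphere_case
        smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
        smap.cost[:] = 0.5
        with pytest.raises(ValueError):
            relative_objective_distribution(smap)


def test_exports_written(tmp_path, sphere_case):
    from needleplan.pathmap import save_surface_map_ply, save_surface_map_vtk

    ph, mask, mesh = sphere_case
    smap = build_surface_map(ph.volume, mesh, ph.spec.center, PathConstraints(), mask)
    vtk = tmp_path / "map.vtk"
    save_surface_map_vtk(smap, vtk)
    text = vtk.read_text()
    assert "POLYDATA" in text and "SCALARS cost" in text
    ply = tmp_path / "map.ply"
    save_surface_map_ply(smap, ply)
    assert ply.stat().st_size > 0
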
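import numpy as np
import pytest

from needleplan import (
    RigidTransform,
    compose_chain,
    detect_fiducials,
    make_fiducial_set,
    make_pose_pairs,
    match_fiducials,
    needle_tip_offset,
    qr24_hand_eye,
    register_ct_to_base,
    rigid_fit,
)
from needleplan.calibration import AmbiguityError, CalibrationError, FitError, MatchError
from needleplan.phantom import fiducial_cad_grid


class TestQR24:
    def test_noiseless_recovery(self):
        pp = make_pose_pairs(60, seed=2)
        res = qr24_hand_eye(pp)
        assert res.x.translation_distance_to(pp.x_true) < 1e-6
        assert res.x.rotation_angle_to(pp.x_true) < 1e-6
        assert res.y.translation_distance_to(pp.y_true) < 1e-6
        assert res.y.rotation_angle_to(pp.y_true) < 1e-6
        assert res.mean_t_err < 1e-6

    def test_noisy_recovery_within_bounds(self):
        pp = make_pose_pairs(60, noise_t=0.1, noise_r=0.1, seed=7)
        res = qr24_hand_eye(pp)
        assert res.x.translation_distance_to(pp.x_true) < 1.0
        assert res.x.rotation_angle_to(pp.x_true) < 0.5
        assert res.y.translation_distance_to(pp.y_true) < 1.0
        assert res.y.rotation_angle_to(pp.y_true) < 0.5

    def test_single_axis_set_rejected(self):
        pp = make_pose_pairs(20, seed=3, axis=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(CalibrationError):
            qr24_hand_eye(pp)

    def test_rotation_projection_residuals_track_noise(self):
        pp = make_pose_pairs(60, noise_t=0.2, noise_r=0.2, seed=11)
        res = qr24_hand_eye(pp)
        # residuals after projection stay at the scale of the injected noise
        assert res.mean_t_err < 5 * 0.2 + 1.0
        assert res.mean_r_err < 5 * 0.2


class TestRigidFit:
    def test_identity(self, rng):
        pts = rng.uniform(-50, 50, size=(10, 3))
        t, rmse = rigid_fit(pts, pts)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)
        assert rmse < 1e-9

    def test_exact_recovery(self, rng):
        true = RigidTransform.random(rng)
        src = rng.uniform(-60, 60, size=(24, 3))
        t, rmse = rigid_fit(src, true.apply(src))
        assert np.abs(t.matrix - true.matrix).max() < 1e-9
        assert rmse < 1e-9

    def test_noise_rmse_bracket(self, rng):
        sigma = 0.3
        true = RigidTransform.random(rng)
        src = rng.uniform(-60, 60, size=(24, 3))
        dst = true.apply(src) + rng.normal(0, sigma, size=(24, 3))
        _, rmse = rigid_fit(src, dst)
        assert 0.5 * sigma * np.sqrt(3) * 0.5 < rmse < 2 * sigma * np.sqrt(3)

    def test_left_invariance(self, rng):
        pre = RigidTransform.random(rng)
        true = RigidTransform.random(rng)
        src = rng.uniform(-60, 60, size=(24, 3))
        dst = true.apply(src) + rng.normal(0, 0.2, size=(24, 3))
        _, rmse1 = rigid_fit(src, dst)
        _, rmse2 = rigid_fit(pre.apply(src), pre.apply(dst))
        assert abs(rmse1 - rmse2) < 1e-9

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(FitError):
            rigid_fit(line, line + 1.0)


class TestMatchFiducials:
    def test_identity_correspondence(self):
        cad, radii = fiducial_cad_grid()
        detected = [(c, 4 / 3 * np.pi * r**3) for c, r in zip(cad, radii)]
        corr = match_fiducials(detected, (cad, radii))
        assert np.array_equal(corr, np.arange(24))

    def test_transformed_shuffled_recovered(self, rng):
        cad, radii = fiducial_cad_grid()
        t = RigidTransform.random(rng)
        perm = rng.permutation(24)
        detected = [(t.apply(cad[i]), 4 / 3 * np.pi * radii[i] ** 3) for i in perm]
        corr = match_fiducials(detected, (cad, radii))
        assert np.array_equal(corr, perm)

    def test_missing_ball_rejected(self):
        cad, radii = fiducial_cad_grid()
        detected = [(c, 4 / 3 * np.pi * r**3) for c, r in zip(cad[:-1], radii[:-1])]
        with pytest.raises(MatchError):
            match_fiducials(detected, (cad, radii))

    def test_symmetric_grid_is_ambiguous(self):
        # a perfectly regular single-class grid has many distance-preserving
        # self-maps: matching must refuse instead of guessing
        xy = np.array([[i * 20.0, j * 20.0, 0.0] for i in range(2) for j in range(2)])
        radii = np.full(4, 5.0)
        detected = [(p, 500.0) for p in xy]
        with pytest.raises(AmbiguityError):
            match_fiducials(detected, (xy, radii))


class TestComposeChain:
    def test_identities_and_inverse(self, rng):
        assert np.allclose(compose_chain([RigidTransform.identity()] * 3).matrix, np.eye(4))
        t = RigidTransform.random(rng)
        assert np.abs(compose_chain([t, t.inverse()]).matrix - np.eye(4)).max() < 1e-12

    def test_known_chain_recovery(self, rng):
        y = RigidTransform.random(rng)
        cam_r = RigidTransform.random(rng)
        r_sb = RigidTransform.random(rng)
        sb_ct = RigidTransform.random(rng)
        truth = y @ cam_r @ r_sb @ sb_ct
        assert np.abs(compose_chain([y, cam_r, r_sb, sb_ct]).matrix - truth.matrix).max() < 1e-9


class TestNeedleTipOffset:
    def test_zero_and_guide_length(self):
        assert np.allclose(needle_tip_offset([0, 0, 0]).matrix, np.eye(4))
        t = needle_tip_offset([0, 0, 190.0])
        assert np.allclose(t.translation, [0, 0, 190.0])
        assert np.allclose(t.rotation, np.eye(3))

    def test_two_path_composition_consistency(self, rng):
        b_ee = RigidTransform.random(rng)
        tip = np.array([1.0, -2.0, 190.0])
        via_chain = (b_ee @ needle_tip_offset(tip)).translation
        direct = b_ee.apply(tip)
        assert np.allclose(via_chain, direct, atol=1e-9)


def test_full_registration_chain_recovers_base_to_ct(rng):
    """Phantom scan -> fiducial detection -> matching -> rigid fit -> chain."""
    fs = make_fiducial_set(seed=13, spacing=0.6)
    detected = detect_fiducials(fs.volume)
    # synthetic tracked pose of the phantom's reflective markers + CAD link
    marker_from_balls = RigidTransform.random(rng, max_translation=40.0)
    y = RigidTransform.random(rng, max_translation=700.0)
    cam_from_marker = RigidTransform.random(rng, max_translation=400.0)
    truth = compose_chain([y, cam_from_marker, marker_from_balls, fs.ct_from_sb.inverse()])
    est, rmse = register_ct_to_base(
        detected, (fs.cad_centers, fs.radii), y, cam_from_marker, marker_from_balls
    )
    assert rmse < 0.2
    assert est.translation_distance_to(truth) < 0.5
    assert est.rotation_angle_to(truth) < 0.1
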
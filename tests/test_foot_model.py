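"""Template geometry, subject scaling and rigid pose fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import footspring as fs
from footspring.foot_model import (PA_SLIPS, SEGMENTS, PoseError, TemplateError,
                                   ScalingError, TemplateConfig, fit_pose_series,
                                   fit_segment_pose, pa_path_points, subject_csa)
from footspring.kinematics import joint_rotation

from conftest import make_static_pose_series


class TestTemplate:
    def test_default_template_structure(self, template):
        assert set(template.segment_markers) == set(SEGMENTS)
        assert set(template.pa_paths) == set(PA_SLIPS)
        assert all(len(p) >= 3 for p in template.pa_paths.values())
        assert template.natural_length_factor == 0.98
        assert template.reference_csa == 69.2

    def test_deterministic_for_fixed_config(self, template):
        other = fs.build_default_template()
        for label in template.marker_labels:
            np.testing.assert_array_equal(template.marker_local[label],
                                          other.marker_local[label])

    def test_two_marker_segment_rejected(self):
        cfg = TemplateConfig()
        cfg.segment_markers["phalanx"] = ("hallux", "mt1_head")
        with pytest.raises(TemplateError, match="phalanx"):
            fs.build_default_template(cfg)

    def test_collinear_segment_rejected(self):
        cfg = TemplateConfig()
        cfg.markers["mt1_head"] = (200.0, 22.0, 22.0)
        cfg.markers["mt5_head"] = (220.0, 22.0, 22.0)  # collinear with hallux
        with pytest.raises(TemplateError, match="collinear"):
            fs.build_default_template(cfg)

    def test_nonpositive_spring_constant_rejected(self):
        with pytest.raises(TemplateError):
            fs.build_default_template(TemplateConfig(spring_constant=-1.0))


class TestSubjectScaling:
    def test_csa_at_reference_mass_is_exact(self, template):
        assert subject_csa(template, template.reference_mass) == pytest.approx(
            69.2, abs=1e-12
        )

    def test_csa_closed_form_at_eightfold_mass(self, template):
        # 8^(2/3) = 4 exactly
        assert subject_csa(template, 8 * template.reference_mass) == pytest.approx(
            4 * 69.2, rel=1e-12
        )

    def test_csa_strictly_increasing_in_mass(self, template):
        masses = np.linspace(40.0, 120.0, 9)
        csas = [subject_csa(template, m) for m in masses]
        assert np.all(np.diff(csas) > 0)

    def test_scaling_idempotence(self, template):
        """A standing trial generated from the template scales back to 1."""
        standing = fs.generate_standing_trial(
            template, fs.Subject("S", "female", 55.0), seed=0
        )
        model = fs.scale_to_subject(template, standing, 55.0)
        for seg in SEGMENTS:
            assert model.segment_scale[seg] == pytest.approx(1.0, abs=1e-9)
            assert model.standing_poses[seg].residual_rms < 1e-9
        assert model.foot_length > 0
        for slip in PA_SLIPS:
            assert model.natural_lengths[slip] == pytest.approx(
                0.98 * model.standing_lengths[slip]
            )
            assert model.natural_lengths[slip] < model.standing_lengths[slip]

    def test_missing_marker_named_in_error(self, template):
        standing = fs.generate_standing_trial(
            template, fs.Subject("S", "female", 55.0), seed=0
        )
        del standing.markers["navicular"]
        with pytest.raises(ScalingError, match="navicular"):
            fs.scale_to_subject(template, standing, 55.0)

    def test_non_static_standing_warns(self, template):
        standing = fs.generate_standing_trial(
            template, fs.Subject("S", "female", 55.0), seed=0
        )
        drift = np.linspace(0, 100, len(standing.marker_time))[:, None] * np.ones(3)
        standing.markers["heel"] = standing.markers["heel"] + drift
        with pytest.warns(UserWarning, match="static"):
            fs.scale_to_subject(template, standing, 55.0)


class TestPoseFitting:
    local = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 80.0, 0.0],
                      [20.0, 30.0, 50.0]])

    def test_identity(self):
        pose = fit_segment_pose(self.local, self.local)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation, 0, atol=1e-9)
        assert pose.residual_rms < 1e-9

    def test_quarter_turn_about_vertical(self):
        r90 = joint_rotation(0.0, 0.0, 90.0)
        pose = fit_segment_pose(self.local, self.local @ r90.T)
        np.testing.assert_allclose(pose.rotation, r90, atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equivariance_under_rigid_motion(self, seed):
        """fit(R X + t) recovers exactly (R, t) with det = +1."""
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation

        r = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-500, 500, 3)
        pose = fit_segment_pose(self.local, self.local @ r.T + t)
        np.testing.assert_allclose(pose.rotation, r, atol=1e-9)
        np.testing.assert_allclose(pose.translation, t, atol=1e-6)
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(pose.rotation.T @ pose.rotation, np.eye(3),
                                   atol=1e-9)

    def test_reflection_corrected_to_proper_rotation(self):
        mirrored = self.local * np.array([1.0, 1.0, -1.0])
        pose = fit_segment_pose(self.local, mirrored)
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_markers_rejected(self):
        with pytest.raises(PoseError):
            fit_segment_pose(self.local[:2], self.local[:2])

    def test_noise_residual_matches_dof_formula(self):
        """Residual RMS under isotropic noise: sigma * sqrt(1 - 6/(3n))."""
        rng = np.random.default_rng(42)
        sigma, n_draws = 0.5, 1000
        local = np.array([[0, 0, 0], [90, 0, 0], [10, 60, 5], [40, -50, 10],
                          [70, 20, 40], [20, 10, 70]], dtype=float)
        n = local.shape[0]
        sq = [
            fit_segment_pose(local, local + rng.normal(0, sigma, local.shape)
                             ).residual_rms ** 2
            for _ in range(n_draws)
        ]
        expected = sigma**2 * (1 - 6 / (3 * n))
        assert np.mean(sq) == pytest.approx(expected, rel=0.06)


class TestPAPathPoints:
    def test_identity_poses_reproduce_reference(self, female_model):
        nf = 4
        poses = {s: make_static_pose_series(nf) for s in SEGMENTS}
        pts = pa_path_points(female_model, poses)
        for slip, path in female_model.pa_paths.items():
            ref = np.array([p for _, p in path])
            np.testing.assert_allclose(pts[slip][0], ref, atol=1e-12)

    def test_translation_equivariance(self, female_model):
        nf = 3
        shift = np.array([10.0, 0.0, 0.0])
        base = {s: make_static_pose_series(nf) for s in SEGMENTS}
        moved = {s: make_static_pose_series(nf, translation=shift) for s in SEGMENTS}
        p0 = pa_path_points(female_model, base)
        p1 = pa_path_points(female_model, moved)
        for slip in PA_SLIPS:
            diff = p1[slip] - p0[slip]
            np.testing.assert_allclose(diff, np.broadcast_to(shift, diff.shape),
                                       atol=1e-12)

    def test_midtarsal_rotation_closed_form(self, female_model):
        """10 degrees of midtarsal dorsiflexion: hindfoot points fixed,
        forefoot/phalanx points follow the hand-computed rotation about the
        joint center."""
        nf = 2
        c = female_model.joint_centers["midtarsal"]
        r = joint_rotation(10.0)
        poses = {
            "hindfoot": make_static_pose_series(nf),
            "forefoot": make_static_pose_series(nf, rotation=r,
                                                translation=c - r @ c),
            "phalanx": make_static_pose_series(nf, rotation=r,
                                               translation=c - r @ c),
        }
        pts = pa_path_points(female_model, poses)
        for slip, path in female_model.pa_paths.items():
            for j, (seg, p) in enumerate(path):
                expected = p if seg == "hindfoot" else r @ (p - c) + c
                np.testing.assert_allclose(pts[slip][0, j], expected, atol=1e-9)

    def test_missing_pose_frame_propagates_nan(self, female_model):
        poses = {s: make_static_pose_series(3) for s in SEGMENTS}
        poses["forefoot"].valid[1] = False
        pts = pa_path_points(female_model, poses)
        assert np.all(np.isnan(pts["PA1"][1]))
        assert np.all(np.isfinite(pts["PA1"][0]))
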
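"""Inverse dynamics against independent statics oracles; powers; normalization."""

import numpy as np
import pytest

import footspring as fs
from footspring import dynamics
from footspring.foot_model import SEGMENTS
from footspring.kinematics import JOINTS, joint_rotation
from footspring.synthetic_data import GRAVITY

from conftest import make_static_pose_series

_DISTAL = {"mtp": ("phalanx",), "midtarsal": ("phalanx", "forefoot"),
           "ankle": ("phalanx", "forefoot", "hindfoot")}


def _zero_wrenches(nf):
    return {s: {"force": np.zeros((nf, 3)), "point": np.zeros((nf, 3)),
                "flagged": np.zeros(nf, dtype=bool)} for s in SEGMENTS}


def statics_oracle_moment(joint, model, inertial, wrenches, poses):
    """Brute-force statics: sum of r x F over gravity and applied loads
    about the joint center, for one static frame; returns the sagittal
    internal moment with the dorsiflexion-positive sign."""
    host = {"mtp": "forefoot", "midtarsal": "hindfoot", "ankle": "hindfoot"}[joint]
    pj = poses[host].pose(0).apply(model.joint_centers[joint][None])[0] / 1000.0
    m_lab = np.zeros(3)
    for seg in _DISTAL[joint]:
        com = poses[seg].pose(0).apply(inertial.com_local[seg][None])[0] / 1000.0
        m_lab += np.cross(com - pj, inertial.mass[seg] * np.array([0, 0, GRAVITY]))
        r = wrenches[seg]["point"][0] / 1000.0 - pj
        m_lab -= np.cross(r, wrenches[seg]["force"][0])
    prox = poses[JOINTS[joint][0]].pose(0).rotation
    m_prox = prox.T @ m_lab
    return -m_prox[1]


class TestStaticsOracle:
    nf = 11

    def _static_setup(self, female_model):
        inertial = dynamics.default_inertial_params(female_model)
        poses = {s: make_static_pose_series(self.nf) for s in SEGMENTS}
        poses["shank"] = make_static_pose_series(self.nf)
        return inertial, poses

    def test_gravity_only_matches_oracle_exactly(self, female_model):
        inertial, poses = self._static_setup(female_model)
        wr = _zero_wrenches(self.nf)
        kin = dynamics.inverse_dynamics(poses, wr, inertial, female_model,
                                        np.arange(self.nf) / 100.0)
        for joint in JOINTS:
            oracle = statics_oracle_moment(joint, female_model, inertial, wr, poses)
            assert kin.moment[joint][5, 0] == pytest.approx(oracle, abs=1e-9)

    def test_applied_load_matches_oracle_exactly(self, female_model):
        inertial, poses = self._static_setup(female_model)
        wr = _zero_wrenches(self.nf)
        wr["forefoot"]["force"][:, 2] = 400.0
        wr["forefoot"]["point"][:] = np.array([180.0, 10.0, 0.0])
        wr["hindfoot"]["force"][:, 2] = 250.0
        wr["hindfoot"]["point"][:] = np.array([-60.0, 0.0, 0.0])
        kin = dynamics.inverse_dynamics(poses, wr, inertial, female_model,
                                        np.arange(self.nf) / 100.0)
        for joint in JOINTS:
            oracle = statics_oracle_moment(joint, female_model, inertial, wr, poses)
            assert kin.moment[joint][5, 0] == pytest.approx(oracle, abs=1e-9)

    def test_point_mass_closed_form(self, female_model):
        """1 kg phalanx, COM 0.1 m anterior of the MTP joint, no GRF: the
        sagittal MTP moment magnitude is m g r = 0.981 N·m."""
        inertial = dynamics.default_inertial_params(female_model)
        inertial.mass["phalanx"] = 1.0
        inertial.com_local["phalanx"] = (
            female_model.joint_centers["mtp"] + np.array([100.0, 0.0, 0.0])
        )
        poses = {s: make_static_pose_series(self.nf) for s in SEGMENTS}
        poses["shank"] = make_static_pose_series(self.nf)
        kin = dynamics.inverse_dynamics(poses, _zero_wrenches(self.nf), inertial,
                                        female_model, np.arange(self.nf) / 100.0)
        assert abs(kin.moment["mtp"][5, 0]) == pytest.approx(0.981, abs=1e-6)

    def test_vertical_load_anterior_of_midtarsal_is_plantarflexion(self, female_model):
        """Vertical force F at COP a distance d anterior of the midtarsal
        joint: the internal moment is plantarflexion of magnitude about F d
        (within 2%, gravity being the small remainder)."""
        inertial, poses = self._static_setup(female_model)
        wr = _zero_wrenches(self.nf)
        F, cop = 500.0, np.array([172.5, -2.0, 35.0])  # 100 mm anterior of joint
        wr["forefoot"]["force"][:, 2] = F
        wr["forefoot"]["point"][:] = cop
        kin = dynamics.inverse_dynamics(poses, wr, inertial, female_model,
                                        np.arange(self.nf) / 100.0)
        got = kin.moment["midtarsal"][5, 0]
        assert got < 0  # plantarflexion
        assert got == pytest.approx(-F * 0.1, rel=0.02)


class TestQuasiStatic:
    def test_slow_motion_matches_statics_within_two_percent(self, female_model):
        """0.25 Hz, 5 deg midtarsal sweep under a constant forefoot load:
        the Newton-Euler moment tracks the statics oracle within 2%."""
        inertial = dynamics.default_inertial_params(female_model)
        rate = 100.0
        t = np.arange(0, 4, 1 / rate)
        nf = len(t)
        c = female_model.joint_centers["midtarsal"]
        rots = np.stack([joint_rotation(5.0 * np.sin(2 * np.pi * 0.25 * ti))
                         for ti in t])
        trans = c - np.einsum("fij,j->fi", rots, c)
        from footspring.foot_model import PoseSeries

        moving = PoseSeries(rots, trans, np.zeros(nf), np.ones(nf, bool))
        poses = {
            "hindfoot": make_static_pose_series(nf),
            "shank": make_static_pose_series(nf),
            "forefoot": moving,
            "phalanx": moving,
        }
        wr = _zero_wrenches(nf)
        wr["forefoot"]["force"][:, 2] = 300.0
        wr["forefoot"]["point"][:] = np.array([160.0, 0.0, 0.0])
        kin = dynamics.inverse_dynamics(poses, wr, inertial, female_model, t)
        # statics oracle frame by frame at a few interior samples
        for i in (57, 101, 223, 307):
            frame_poses = {
                s: make_static_pose_series(1, rotation=poses[s].rotation[i],
                                           translation=poses[s].translation[i])
                for s in poses
            }
            frame_wr = {s: {k: v[i:i + 1] for k, v in wr[s].items()}
                        for s in SEGMENTS}
            oracle = statics_oracle_moment("midtarsal", female_model, inertial,
                                           frame_wr, frame_poses)
            assert kin.moment["midtarsal"][i, 0] == pytest.approx(oracle, rel=0.02)


class TestWrenchAssignment:
    def test_posterior_only_load_leaves_forefoot_unloaded(self, template):
        trial = fs.generate_standing_trial(
            template, fs.Subject("S", "female", 55.0), seed=0, anterior_share=0.0
        )
        wr = dynamics.assign_plate_wrenches(trial)
        assert np.all(wr["forefoot"]["force"] == 0.0)
        assert np.all(wr["hindfoot"]["force"][:, 2] > 0)

    def test_static_total_force_is_body_weight(self, template):
        mass = 55.0
        trial = fs.generate_standing_trial(
            template, fs.Subject("S", "female", mass), seed=0, anterior_share=0.4
        )
        wr = dynamics.assign_plate_wrenches(trial)
        total = wr["forefoot"]["force"][:, 2] + wr["hindfoot"]["force"][:, 2]
        np.testing.assert_allclose(total, mass * GRAVITY, atol=1e-6)

    def test_cop_outside_plate_flagged(self, template):
        trial = fs.generate_standing_trial(
            template, fs.Subject("S", "female", 55.0), seed=0, anterior_share=0.5
        )
        trial.plates[1].cop[:] = np.array([900.0, 0.0])  # beyond the corner
        wr = dynamics.assign_plate_wrenches(trial)
        assert wr["forefoot"]["flagged"].any()


class TestPowerAndNormalization:
    def test_zero_velocity_zero_power(self, female_run):
        kin = female_run["result"].kinetics
        zero_w = {j: np.zeros_like(m) for j, m in kin.moment.items()}
        out = dynamics.joint_power(kin, zero_w)
        for p in out.power.values():
            np.testing.assert_allclose(p, 0.0)

    def test_sagittal_absorption_sign(self):
        kin = dynamics.JointKineticsSeries(
            time=np.zeros(1), moment={"midtarsal": np.array([[-2.0, 0.0, 0.0]])}
        )
        w = {"midtarsal": np.array([[np.rad2deg(1.0), 0.0, 0.0]])}  # +1 rad/s
        out = dynamics.joint_power(kin, w)
        assert out.power["midtarsal"][0] == pytest.approx(-2.0)

    def test_drop_jump_power_sign_structure(self, female_run):
        """Landing: plantarflexion moment with dorsiflexion velocity absorbs
        energy; push-off: plantarflexion moment with plantarflexion velocity
        generates it."""
        s = female_run["result"].scalars
        assert s["midtarsal_moment_norm@T2"] < 0
        assert s["midtarsal_sagittal_velocity_degs@T2"] > 0
        assert s["midtarsal_power_wkg@T2"] < 0
        assert s["midtarsal_sagittal_velocity_degs@T4"] < 0
        assert s["midtarsal_power_wkg@T4"] > 0

    def test_moment_normalization_arithmetic(self):
        out = dynamics.normalize(np.array([3.42]), "foot_moment", 60.0, 0.24)
        assert out.values[0] == pytest.approx(0.2375)
        assert out.units == "N·m/(kg·m)"

    def test_grf_normalization_of_body_weight_is_one(self):
        out = dynamics.normalize(np.array([60.0 * GRAVITY]), "grf", 60.0)
        assert out.values[0] == pytest.approx(1.0)

    def test_double_normalization_rejected(self):
        once = dynamics.normalize(np.array([1.0]), "power", 60.0)
        with pytest.raises(ValueError, match="already normalized"):
            dynamics.normalize(once, "power", 60.0)

    def test_nonpositive_normalizers_rejected(self):
        with pytest.raises(ValueError):
            dynamics.normalize(np.array([1.0]), "grf", 0.0)
        with pytest.raises(ValueError):
            dynamics.normalize(np.array([1.0]), "foot_moment", 60.0, -0.2)

    def test_inertial_validation(self, female_model):
        inertial = dynamics.default_inertial_params(female_model)
        bad = {**inertial.mass, "phalanx": -0.1}
        with pytest.raises(ValueError, match="positive"):
            dynamics.InertialParams(bad, inertial.com_local, inertial.inertia_local)
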
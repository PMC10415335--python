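"""Newton-Euler inverse dynamics across the three foot segments.

The two-plate ground reaction wrenches are assigned to the segments that
land on them (anterior plate -> forefoot, posterior plate -> hindfoot), the
analog channels are block-averaged down to the marker rate, and joint
moments are computed by a distal-to-proximal recursion: the phalanx load
path gives the MTP moment, phalanx+forefoot the midtarsal moment, and all
three segments the ankle moment.  Moments are reported about the joint
center, resolved in the proximal-segment frame, with the same
dorsiflexion-positive sign convention as the joint angles.

Segment inertial parameters are not measurable from markers; defaults
follow conventional anthropometry (foot mass = 1.37% body mass, split
hindfoot/forefoot/phalanx 60/30/10%, COM at the segment marker centroid,
inertia of a solid ellipsoid spanning the segment markers) and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.transform import Rotation

from .foot_model import SEGMENTS, PoseSeries, SubjectModel
from .kinematics import JOINTS, _SIGNS, differentiate

GRAVITY = 9.81

__all__ = [
    "InertialParams",
    "default_inertial_params",
    "assign_plate_wrenches",
    "downsample_analog",
    "angular_velocity",
    "inverse_dynamics",
    "joint_power",
    "normalize",
    "NormalizedSeries",
    "JointKineticsSeries",
]

#: load path of each joint: the set of segments distal to it
_DISTAL_SETS = {
    "mtp": ("phalanx",),
    "midtarsal": ("phalanx", "forefoot"),
    "ankle": ("phalanx", "forefoot", "hindfoot"),
}

#: segment whose pose carries the joint center
_JOINT_HOST = {"mtp": "forefoot", "midtarsal": "hindfoot", "ankle": "hindfoot"}


@dataclass
class InertialParams:
    """Per-segment mass [kg], COM [mm, segment frame], inertia [kg·m²]."""

    mass: dict  # segment -> kg
    com_local: dict  # segment -> (3,) mm
    inertia_local: dict  # segment -> (3, 3) kg·m² about the COM

    def __post_init__(self):
        for seg in SEGMENTS:
            if self.mass[seg] <= 0:
                raise ValueError(f"mass of {seg} must be positive")
            inertia = np.asarray(self.inertia_local[seg])
            if not np.allclose(inertia, inertia.T, atol=1e-12):
                raise ValueError(f"inertia tensor of {seg} must be symmetric")
            if np.any(np.linalg.eigvalsh(inertia) < -1e-15):
                raise ValueError(f"inertia tensor of {seg} must be PSD")


def default_inertial_params(model: SubjectModel,
                            foot_mass_fraction: float = 0.0137,
                            split=(0.10, 0.30, 0.60)) -> InertialParams:
    """Anthropometric defaults; ``split`` is (phalanx, forefoot, hindfoot)."""
    foot_mass = foot_mass_fraction * model.body_mass
    masses = dict(zip(("phalanx", "forefoot", "hindfoot"), split))
    mass = {seg: foot_mass * frac for seg, frac in masses.items()}
    com = {}
    inertia = {}
    for seg in SEGMENTS:
        pts = model.segment_local_markers(seg)
        com[seg] = pts.mean(axis=0)
        semi = np.maximum((pts.max(axis=0) - pts.min(axis=0)) / 2.0, 8.0) / 1000.0
        a, b, c = semi
        m = mass[seg]
        inertia[seg] = np.diag([
            m / 5.0 * (b**2 + c**2),
            m / 5.0 * (a**2 + c**2),
            m / 5.0 * (a**2 + b**2),
        ])
    return InertialParams(mass, com, inertia)


# --------------------------------------------------------------------------
# Plate wrench assignment
# --------------------------------------------------------------------------

def downsample_analog(series: np.ndarray, n_frames: int) -> np.ndarray:
    """Analog (1000 Hz) -> marker rate (100 Hz) by 10-sample block averaging.

    A centered moving average (anti-alias) is sampled at every tenth sample.
    """
    y = np.asarray(series, dtype=float)
    smooth = uniform_filter1d(y, size=10, axis=0, mode="nearest")
    idx = np.arange(n_frames) * 10
    idx = np.minimum(idx, y.shape[0] - 1)
    return smooth[idx]


def assign_plate_wrenches(trial, force_floor_n: float = 20.0) -> dict:
    """External GRF per segment at the marker rate.

    Returns ``segment -> {"force": (F,3) N, "point": (F,3) mm,
    "flagged": (F,) bool}``.  The anterior plate loads the forefoot at its
    COP, the posterior plate the hindfoot; a frame is flagged when the COP
    leaves the plate polygon while the plate carries force.
    """
    nf = len(trial.marker_time)
    out = {seg: {"force": np.zeros((nf, 3)),
                 "point": np.zeros((nf, 3)),
                 "flagged": np.zeros(nf, dtype=bool)} for seg in SEGMENTS}
    for plate_series, seg in ((trial.plates[1], "forefoot"),
                              (trial.plates[0], "hindfoot")):
        force = downsample_analog(plate_series.force, nf)
        cop = downsample_analog(np.nan_to_num(plate_series.cop), nf)
        loaded = force[:, 2] > force_floor_n
        out[seg]["force"] = np.where(loaded[:, None], force, 0.0)
        pt = np.zeros((nf, 3))
        pt[:, :2] = cop
        out[seg]["point"] = pt
        inside = plate_series.plate.contains(cop)
        out[seg]["flagged"] = loaded & ~inside
    return out


# --------------------------------------------------------------------------
# Inverse dynamics
# --------------------------------------------------------------------------

def angular_velocity(poses: PoseSeries, dt: float) -> np.ndarray:
    """Lab-frame angular velocity [rad/s] from a rotation series.

    Central rotation increments: omega_i = rotvec(R_{i+1} R_{i-1}^T) / (2 dt),
    one-sided at the ends.
    """
    r = poses.rotation
    nf = r.shape[0]
    if nf < 3:
        raise ValueError("need at least 3 frames")
    omega = np.zeros((nf, 3))
    rel = np.einsum("fij,fkj->fik", r[2:], r[:-2])  # R_{i+1} @ R_{i-1}^T
    omega[1:-1] = Rotation.from_matrix(rel).as_rotvec() / (2.0 * dt)
    omega[0] = Rotation.from_matrix(r[1] @ r[0].T).as_rotvec() / dt
    omega[-1] = Rotation.from_matrix(r[-1] @ r[-2].T).as_rotvec() / dt
    return omega


@dataclass
class JointKineticsSeries:
    """Joint moments [N·m] (proximal frame, dorsiflexion positive) and powers [W]."""

    time: np.ndarray
    moment: dict  # joint -> (F, 3) N·m, (sagittal, frontal, transverse)
    power: dict | None = None  # joint -> (F,) W


def inverse_dynamics(poses: dict, wrenches: dict, inertial: InertialParams,
                     model: SubjectModel, time: np.ndarray) -> JointKineticsSeries:
    """Distal-to-proximal Newton-Euler joint moments.

    ``poses`` must contain PoseSeries for the three foot segments and the
    shank (proximal frame of the ankle).  For each joint the aggregate of
    all distal segments must balance gravity, the assigned plate wrenches
    and its inertial terms; the residual is the internal joint moment about
    the joint center, reported in the proximal-segment frame with
    dorsiflexion positive.
    """
    time = np.asarray(time, dtype=float)
    dt = float(np.mean(np.diff(time)))
    nf = len(time)
    g = np.array([0.0, 0.0, -GRAVITY])

    # per-segment kinematics in SI units
    com = {}
    acc = {}
    omega = {}
    alpha = {}
    inertia_lab = {}
    for seg in SEGMENTS:
        ps = poses[seg]
        com_lab = ps.apply(inertial.com_local[seg][None])[:, 0, :] / 1000.0  # m
        com[seg] = com_lab
        vel = differentiate(com_lab, dt)
        acc[seg] = differentiate(vel, dt)
        omega[seg] = angular_velocity(ps, dt)
        alpha[seg] = differentiate(omega[seg], dt)
        inertia_lab[seg] = np.einsum(
            "fij,jk,flk->fil", ps.rotation, inertial.inertia_local[seg], ps.rotation
        )

    moments = {}
    for joint, dist_set in _DISTAL_SETS.items():
        host = poses[_JOINT_HOST[joint]]
        p_j = host.apply(model.joint_centers[joint][None])[:, 0, :] / 1000.0  # m

        m_lab = np.zeros((nf, 3))
        for seg in dist_set:
            m_seg = inertial.mass[seg]
            # inertial torque about the COM
            m_lab += np.einsum("fij,fj->fi", inertia_lab[seg], alpha[seg])
            m_lab += np.cross(omega[seg],
                              np.einsum("fij,fj->fi", inertia_lab[seg], omega[seg]))
            # transport of the net force (ma - mg) to the joint center
            m_lab += np.cross(com[seg] - p_j, m_seg * (acc[seg] - g))
            # external plate wrench applied at its COP
            w = wrenches[seg]
            r = w["point"] / 1000.0 - p_j
            m_lab -= np.cross(r, w["force"])

        prox_rot = poses[JOINTS[joint][0]].rotation
        m_prox = np.einsum("fji,fj->fi", prox_rot, m_lab)
        # map (x, y, z) components to (sagittal, frontal, transverse) with
        # the dorsiflexion/eversion/abduction-positive sign convention
        moments[joint] = np.stack([
            _SIGNS[0] * m_prox[:, 1],
            _SIGNS[1] * m_prox[:, 0],
            _SIGNS[2] * m_prox[:, 2],
        ], axis=1)

    return JointKineticsSeries(time=time, moment=moments)


def joint_power(kinetics: JointKineticsSeries, angular_velocity_deg: dict) -> JointKineticsSeries:
    """Joint power [W]: moment · angular velocity (per-plane dot product).

    ``angular_velocity_deg`` maps joint -> (F, 3) deg/s in the same
    (sagittal, frontal, transverse) components as the moments; degrees are
    converted to radians internally.
    """
    power = {}
    for joint, m in kinetics.moment.items():
        w = np.deg2rad(np.asarray(angular_velocity_deg[joint], dtype=float))
        if w.shape != m.shape:
            raise ValueError(f"{joint}: angular velocity shape {w.shape} != moment {m.shape}")
        power[joint] = np.einsum("fi,fi->f", m, w)
    return JointKineticsSeries(time=kinetics.time, moment=kinetics.moment, power=power)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

@dataclass
class NormalizedSeries:
    """Unit-tagged normalized series; normalizing twice is an error."""

    values: np.ndarray
    kind: str
    units: str


def normalize(series, kind: str, body_mass: float, foot_length: float | None = None):
    """Normalize a series: foot moments by (body mass x foot length), powers
    by body mass, GRFs by body weight.

    ``kind`` is one of ``foot_moment`` -> N·m/(kg·m), ``power`` -> W/kg,
    ``grf`` -> BW.
    """
    if isinstance(series, NormalizedSeries):
        raise ValueError(f"series already normalized ({series.kind})")
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    y = np.asarray(series, dtype=float)
    if kind == "foot_moment":
        if foot_length is None or foot_length <= 0:
            raise ValueError("foot length must be positive for moment normalization")
        return NormalizedSeries(y / (body_mass * foot_length), kind, "N·m/(kg·m)")
    if kind == "power":
        return NormalizedSeries(y / body_mass, kind, "W/kg")
    if kind == "grf":
        return NormalizedSeries(y / (body_mass * GRAVITY), kind, "BW")
    raise ValueError(f"unknown normalization kind {kind!r}")
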
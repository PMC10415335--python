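"""Marker filtering, joint angles and angular velocities.

Joint angles are Euler decompositions of the relative rotation of the distal
segment with respect to the proximal one, in the order sagittal -> frontal ->
transverse (flexion axis first), zeroed at the quiet-standing posture.  Sign
conventions for the right side: positive = dorsiflexion, eversion, abduction.

The ankle uses a shank frame constructed from the two malleolus markers and a
synthetic marker on the shank axis (the malleoli are physically attached to
the hindfoot, so a Procrustes fit is not applicable to the shank; the frame
is built geometrically instead and documented as a proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .foot_model import SEGMENTS, PoseError, PoseSeries, SubjectModel, fit_pose_series

__all__ = [
    "JOINTS",
    "EULER_SEQ",
    "JointAngleSeries",
    "lowpass_filter",
    "differentiate",
    "joint_rotation",
    "rotation_angles",
    "shank_pose_series",
    "fit_trial_poses",
    "joint_angles",
    "standing_reference",
]

#: joint -> (proximal segment, distal segment)
JOINTS = {
    "mtp": ("forefoot", "phalanx"),
    "midtarsal": ("hindfoot", "forefoot"),
    "ankle": ("shank", "hindfoot"),
}

#: Intrinsic Euler sequence: mediolateral (sagittal) axis first, then
#: anteroposterior (frontal), then vertical (transverse).
EULER_SEQ = "YXZ"

# Right-side sign map from raw YXZ Euler angles to (dorsiflexion, eversion,
# abduction)-positive joint angles.
_SIGNS = np.array([-1.0, -1.0, -1.0])

GIMBAL_LIMIT_DEG = 85.0


def lowpass_filter(series: np.ndarray, rate: float, cutoff: float = 24.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``series`` is filtered along axis 0 (time).  Defaults are a fourth-order
    filter at 24 Hz; the effective response of the two passes is the squared
    magnitude, so the -6 dB point sits at the cutoff.  Force-plate channels
    are deliberately never passed through this filter.
    """
    y = np.asarray(series, dtype=float)
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {rate / 2:.1f} Hz")
    if y.shape[0] <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, y, axis=0)


def differentiate(series: np.ndarray, timestep: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at the ends."""
    y = np.asarray(series, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    return np.gradient(y, timestep, axis=0)


# --------------------------------------------------------------------------
# Euler decomposition
# --------------------------------------------------------------------------

def joint_rotation(sagittal: float, frontal: float = 0.0, transverse: float = 0.0,
                   degrees: bool = True) -> np.ndarray:
    """Relative rotation matrix (distal w.r.t. proximal) from joint angles."""
    ang = np.array([sagittal, frontal, transverse], dtype=float) * _SIGNS
    return Rotation.from_euler(EULER_SEQ, ang, degrees=degrees).as_matrix()


def rotation_angles(rel: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Joint angles (sagittal, frontal, transverse) from a relative rotation.

    Accepts a single ``(3, 3)`` matrix or a stack ``(F, 3, 3)``.
    """
    r = Rotation.from_matrix(rel)
    ang = r.as_euler(EULER_SEQ, degrees=degrees)
    return ang * _SIGNS


# --------------------------------------------------------------------------
# Pose series from markers
# --------------------------------------------------------------------------

def fit_trial_poses(markers: dict, model: SubjectModel) -> dict:
    """Fit per-frame rigid poses of the three foot segments from markers.

    ``markers`` maps label -> (F, 3) lab trajectories in mm (already
    filtered).  Returns segment -> :class:`PoseSeries`, including a
    ``"shank"`` entry built by :func:`shank_pose_series`.
    """
    poses = {}
    for seg in SEGMENTS:
        labels = model.template.segment_markers[seg]
        missing = [m for m in labels if m not in markers]
        if missing:
            raise PoseError(f"segment {seg!r} is missing markers {missing}")
        local = model.segment_local_markers(seg)
        obs = np.stack([np.asarray(markers[m], dtype=float) for m in labels], axis=1)
        poses[seg] = fit_pose_series(local, obs)
    poses["shank"] = shank_pose_series(markers, model)
    return poses


def _shank_basis(med: np.ndarray, lat: np.ndarray, shank: np.ndarray):
    """Orthonormal shank basis from the malleoli and the shank-axis point.

    Returns (basis matrix with columns X, Y, Z; ankle center).  Z points up
    the shank axis, Y along the medial->lateral malleolar line (medial
    positive), X completes the right-handed frame.
    """
    center = 0.5 * (med + lat)
    z = shank - center
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    z = z / nz
    y = med - lat
    y = y / np.linalg.norm(y, axis=-1, keepdims=True)
    x = np.cross(y, z)
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    y = np.cross(z, x)
    basis = np.stack([x, y, z], axis=-1)
    return basis, center


def shank_pose_series(markers: dict, model: SubjectModel,
                      shank_label: str = "shank_axis") -> PoseSeries:
    """Shank frame per frame from malleoli + synthetic shank-axis marker."""
    needed = ["med_malleolus", "lat_malleolus", shank_label]
    missing = [m for m in needed if m not in markers]
    if missing:
        raise PoseError(f"shank frame is missing markers {missing}")
    med = np.asarray(markers["med_malleolus"], dtype=float)
    lat = np.asarray(markers["lat_malleolus"], dtype=float)
    shk = np.asarray(markers[shank_label], dtype=float)

    b, center = _shank_basis(med, lat, shk)
    b0, c0 = _shank_basis(
        model.marker_local["med_malleolus"],
        model.marker_local["lat_malleolus"],
        model.shank_marker,
    )
    rot = b @ b0.T  # (F, 3, 3)
    tra = center - np.einsum("fij,j->fi", rot, c0)
    valid = np.all(np.isfinite(med) & np.isfinite(lat) & np.isfinite(shk), axis=1)
    rms = np.zeros(len(valid))
    rot = np.where(valid[:, None, None], rot, np.nan)
    tra = np.where(valid[:, None], tra, np.nan)
    return PoseSeries(rot, tra, rms, valid)


# --------------------------------------------------------------------------
# Joint angles
# --------------------------------------------------------------------------

@dataclass
class JointAngleSeries:
    """Per-joint angle time series [deg], standing reference subtracted.

    ``angles[joint]`` is an ``(F, 3)`` array with columns (sagittal,
    frontal, transverse); positive = dorsiflexion, eversion, abduction.
    ``gimbal[joint]`` flags frames with |frontal| beyond the gimbal guard.
    """

    time: np.ndarray
    angles: dict
    gimbal: dict = field(default_factory=dict)

    def velocity(self, rate: float) -> dict:
        """Angular velocity [deg/s] per joint by differentiating the angles."""
        return {j: differentiate(a, 1.0 / rate) for j, a in self.angles.items()}


def _relative_angles(poses: dict) -> dict:
    out = {}
    gim = {}
    for joint, (prox, dist) in JOINTS.items():
        pp, pd = poses[prox], poses[dist]
        nf = pd.n_frames
        ang = np.full((nf, 3), np.nan)
        ok = pp.valid & pd.valid
        if np.any(ok):
            rel = np.einsum("fji,fjk->fik", pp.rotation[ok], pd.rotation[ok])
            ang[ok] = rotation_angles(rel)
        out[joint] = ang
        gim[joint] = np.abs(ang[:, 1]) > GIMBAL_LIMIT_DEG
    return out, gim


def joint_angles(poses: dict, time: np.ndarray,
                 reference: dict | None = None) -> JointAngleSeries:
    """Euler joint angles from segment pose series.

    ``reference`` maps joint -> (3,) standing angles subtracted componentwise
    so that the quiet-standing posture reads zero.
    """
    ang, gim = _relative_angles(poses)
    if reference is not None:
        ang = {j: a - np.asarray(reference[j], dtype=float) for j, a in ang.items()}
    return JointAngleSeries(np.asarray(time, dtype=float), ang, gim)


def standing_reference(model: SubjectModel, standing) -> dict:
    """Standing joint angles (joint -> (3,) deg) for zeroing.

    Computed by running the same pose-fitting + Euler machinery on the
    time-averaged standing markers.
    """
    mean_markers = {
        label: np.asarray(traj, dtype=float).mean(axis=0, keepdims=True)
        for label, traj in standing.markers.items()
    }
    poses = fit_trial_poses(mean_markers, model)
    ang, _ = _relative_angles(poses)
    return {j: a[0] for j, a in ang.items()}
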
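"""Three-segment foot model with plantar-aponeurosis (PA) spring paths.

The foot is modelled as three rigid segments — phalanx (toes), forefoot and
hindfoot — connected at the metatarsophalangeal (MTP) and midtarsal joints,
with the ankle joining the hindfoot to a shank frame.  The plantar
aponeurosis is represented by five tension-only linear springs (PA1 medial to
PA5 lateral), each routed from an origin on the hindfoot through at least one
intermediate point on the forefoot to an insertion on the phalanx.

Because the original CT-derived geometry is not published, this module ships
a parametric idealized template: marker and PA-path coordinates for an
average right foot, expressed in a common neutral (quiet-standing)
configuration.  Each segment's local frame coincides with the lab frame in
that neutral pose, so standing poses are the identity by construction.

Lab frame convention (stated in all file I/O): right-handed, X anterior
(walking direction), Y to the subject's left, Z up.  Units: marker and PA
coordinates in mm, masses in kg, spring constants in N/mm.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SEGMENTS",
    "PA_SLIPS",
    "MARKER_NUMBERS",
    "TemplateError",
    "ScalingError",
    "PoseError",
    "TemplateConfig",
    "FootTemplate",
    "SubjectModel",
    "RigidPose",
    "PoseSeries",
    "build_default_template",
    "fit_segment_pose",
    "fit_similarity",
    "scale_to_subject",
    "pa_path_points",
]

SEGMENTS = ("phalanx", "forefoot", "hindfoot")
PA_SLIPS = ("PA1", "PA2", "PA3", "PA4", "PA5")

#: Foot marker numbering (right side).  Marker #7 is the fifth metatarsal
#: base (it pairs with the navicular in the force-plate placement rule).
MARKER_NUMBERS = {
    "hallux": 1,
    "mt1_head": 2,
    "mt1_base": 3,
    "mt2_head": 4,
    "mt2_base": 5,
    "mt5_head": 6,
    "mt5_base": 7,
    "navicular": 8,
    "med_malleolus": 9,
    "lat_malleolus": 10,
    "sustentaculum": 11,
    "peroneal_tubercle": 12,
    "heel": 13,
    "calcaneus_sup": 14,
}


class TemplateError(ValueError):
    """Invalid or degenerate foot-template geometry."""


class ScalingError(ValueError):
    """Subject scaling failed (e.g. a required marker is missing)."""


class PoseError(ValueError):
    """Rigid pose fitting is under-determined or inconsistent."""


# --------------------------------------------------------------------------
# Template configuration
# --------------------------------------------------------------------------

# Idealized right-foot geometry in the neutral standing configuration [mm].
# Heel near the origin, toes at +X, medial side at +Y (right foot).
_DEFAULT_MARKERS = {
    # phalanx
    "hallux": (240.0, 22.0, 22.0),
    "mt1_head": (180.0, 30.0, 28.0),
    "mt5_head": (170.0, -40.0, 20.0),
    # forefoot
    "mt1_base": (120.0, 25.0, 35.0),
    "mt2_head": (185.0, 5.0, 25.0),
    "mt2_base": (125.0, 8.0, 38.0),
    "mt5_base": (115.0, -35.0, 25.0),
    "navicular": (95.0, 28.0, 40.0),
    # hindfoot
    "med_malleolus": (60.0, 25.0, 68.0),
    "lat_malleolus": (60.0, -30.0, 68.0),
    "sustentaculum": (45.0, 30.0, 35.0),
    "peroneal_tubercle": (50.0, -32.0, 30.0),
    "heel": (0.0, 0.0, 25.0),
    "calcaneus_sup": (10.0, 0.0, 60.0),
}

# In this idealized template the first and fifth metatarsal-head markers are
# carried by the phalanx segment so that every segment has three
# non-collinear markers (the real toe segment carries a single marker, which
# leaves its pose indeterminate).
_DEFAULT_SEGMENT_MARKERS = {
    "phalanx": ("hallux", "mt1_head", "mt5_head"),
    "forefoot": ("mt1_base", "mt2_head", "mt2_base", "mt5_base", "navicular"),
    "hindfoot": (
        "med_malleolus",
        "lat_malleolus",
        "sustentaculum",
        "peroneal_tubercle",
        "heel",
        "calcaneus_sup",
    ),
}

# PA slip paths: (host segment, neutral coordinates [mm]), origin -> insertion.
_DEFAULT_PA_PATHS = {
    "PA1": [
        ("hindfoot", (15.0, 18.0, 8.0)),
        ("forefoot", (140.0, 20.0, 9.0)),
        ("phalanx", (205.0, 24.0, 10.0)),
    ],
    "PA2": [
        ("hindfoot", (15.0, 9.0, 6.0)),
        ("forefoot", (142.0, 10.0, 8.0)),
        ("phalanx", (203.0, 12.0, 9.0)),
    ],
    "PA3": [
        ("hindfoot", (15.0, 0.0, 5.0)),
        ("forefoot", (143.0, 0.0, 8.0)),
        ("phalanx", (200.0, 0.0, 9.0)),
    ],
    "PA4": [
        ("hindfoot", (15.0, -10.0, 5.0)),
        ("forefoot", (141.0, -12.0, 7.0)),
        ("phalanx", (196.0, -14.0, 8.0)),
    ],
    "PA5": [
        ("hindfoot", (15.0, -20.0, 6.0)),
        ("forefoot", (138.0, -25.0, 7.0)),
        ("phalanx", (190.0, -28.0, 8.0)),
    ],
}

# Joint centers in the neutral configuration: MTP = midpoint of the first and
# second metatarsal heads; midtarsal = midpoint navicular/peroneal tubercle;
# ankle = midpoint of the malleoli.
_DEFAULT_JOINT_CENTERS = {
    "mtp": (182.5, 17.5, 26.5),
    "midtarsal": (72.5, -2.0, 35.0),
    "ankle": (60.0, -2.5, 68.0),
}

#: Synthetic marker on the shank axis, directly above the ankle center in the
#: neutral pose; together with the malleoli it defines the shank frame used
#: as the proximal frame of the ankle joint.
_DEFAULT_SHANK_MARKER = (60.0, -2.5, 420.0)


@dataclass
class TemplateConfig:
    """Parameters of the idealized foot template.

    All geometry is expressed in the neutral standing configuration in mm.
    ``spring_constant`` applies to every slip unless ``spring_constants``
    gives per-slip values.
    """

    markers: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_MARKERS))
    segment_markers: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_SEGMENT_MARKERS)
    )
    pa_paths: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_PA_PATHS))
    joint_centers: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_JOINT_CENTERS)
    )
    shank_marker: tuple = _DEFAULT_SHANK_MARKER
    spring_constant: float = 40.0  # N/mm, per slip
    spring_constants: dict | None = None
    natural_length_factor: float = 0.98
    reference_csa: float = 69.2  # mm^2
    reference_mass: float = 70.0  # kg
    csa_split: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)  # share of A_subj per slip
    heel_marker: str = "heel"
    toe_marker: str = "hallux"


@dataclass
class FootTemplate:
    """Validated template geometry plus PA spring parameters."""

    marker_local: dict  # label -> (3,) ndarray [mm], per-segment local frame
    segment_markers: dict  # segment -> tuple of labels
    pa_paths: dict  # slip -> list of (segment, (3,) ndarray)
    joint_centers: dict  # joint -> (3,) ndarray
    shank_marker: np.ndarray
    spring_constants: dict  # slip -> N/mm
    natural_length_factor: float
    reference_csa: float
    reference_mass: float
    csa_split: dict  # slip -> fraction of subject CSA
    heel_marker: str
    toe_marker: str

    def segment_of(self, label: str) -> str:
        for seg, labels in self.segment_markers.items():
            if label in labels:
                return seg
        raise KeyError(label)

    @property
    def marker_labels(self) -> tuple:
        out = []
        for seg in SEGMENTS:
            out.extend(self.segment_markers[seg])
        return tuple(out)

    def to_json(self) -> str:
        payload = {
            "schema": "footspring.template/1",
            "units": {"length": "mm", "mass": "kg", "stiffness": "N/mm"},
            "frame": "X anterior, Y left, Z up (right-handed)",
            "marker_local": {k: list(map(float, v)) for k, v in self.marker_local.items()},
            "segment_markers": {k: list(v) for k, v in self.segment_markers.items()},
            "pa_paths": {
                s: [[seg, list(map(float, p))] for seg, p in path]
                for s, path in self.pa_paths.items()
            },
            "joint_centers": {k: list(map(float, v)) for k, v in self.joint_centers.items()},
            "shank_marker": list(map(float, self.shank_marker)),
            "spring_constants": {k: float(v) for k, v in self.spring_constants.items()},
            "natural_length_factor": self.natural_length_factor,
            "reference_csa": self.reference_csa,
            "reference_mass": self.reference_mass,
            "csa_split": {k: float(v) for k, v in self.csa_split.items()},
            "heel_marker": self.heel_marker,
            "toe_marker": self.toe_marker,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def build_default_template(config: TemplateConfig | None = None) -> FootTemplate:
    """Build and validate a :class:`FootTemplate` from a config.

    Deterministic for a fixed config.  Raises :class:`TemplateError` on
    degenerate geometry (fewer than three markers on a segment, collinear
    segment markers, malformed PA paths, non-positive parameters).
    """
    cfg = config or TemplateConfig()

    seen = set()
    for seg in SEGMENTS:
        labels = tuple(cfg.segment_markers.get(seg, ()))
        if len(labels) < 3:
            raise TemplateError(
                f"segment {seg!r} has {len(labels)} markers; at least 3 "
                "non-collinear markers are required for a determinate pose"
            )
        missing = [m for m in labels if m not in cfg.markers]
        if missing:
            raise TemplateError(f"segment {seg!r} references unknown markers {missing}")
        pts = np.array([cfg.markers[m] for m in labels], dtype=float)
        if _collinear(pts):
            raise TemplateError(f"markers of segment {seg!r} are collinear")
        dup = seen.intersection(labels)
        if dup:
            raise TemplateError(f"markers {sorted(dup)} assigned to more than one segment")
        seen.update(labels)

    if set(cfg.pa_paths) != set(PA_SLIPS):
        raise TemplateError(f"PA paths must be exactly {PA_SLIPS}, got {sorted(cfg.pa_paths)}")
    pa_paths = {}
    for slip in PA_SLIPS:
        path = cfg.pa_paths[slip]
        if len(path) < 3:
            raise TemplateError(f"{slip} path has {len(path)} points; need >= 3")
        hosts = [seg for seg, _ in path]
        bad = [h for h in hosts if h not in SEGMENTS]
        if bad:
            raise TemplateError(f"{slip} path hosted on unknown segments {bad}")
        if hosts[0] != "hindfoot" or hosts[-1] != "phalanx" or "forefoot" not in hosts[1:-1]:
            raise TemplateError(
                f"{slip} must run origin(hindfoot) -> intermediate(forefoot) -> "
                f"insertion(phalanx); got hosts {hosts}"
            )
        pa_paths[slip] = [(seg, np.asarray(p, dtype=float)) for seg, p in path]

    if cfg.spring_constants is not None:
        ks = {s: float(cfg.spring_constants[s]) for s in PA_SLIPS}
    else:
        ks = {s: float(cfg.spring_constant) for s in PA_SLIPS}
    if any(k <= 0 for k in ks.values()):
        raise TemplateError("spring constants must be positive")
    if not (0.0 < cfg.natural_length_factor <= 1.0):
        raise TemplateError("natural_length_factor must be in (0, 1]")
    if cfg.reference_csa <= 0 or cfg.reference_mass <= 0:
        raise TemplateError("reference CSA and mass must be positive")
    split = np.asarray(cfg.csa_split, dtype=float)
    if split.shape != (5,) or np.any(split <= 0) or abs(split.sum() - 1.0) > 1e-9:
        raise TemplateError("csa_split must be 5 positive fractions summing to 1")

    return FootTemplate(
        marker_local={k: np.asarray(v, dtype=float) for k, v in cfg.markers.items()},
        segment_markers={s: tuple(cfg.segment_markers[s]) for s in SEGMENTS},
        pa_paths=pa_paths,
        joint_centers={k: np.asarray(v, dtype=float) for k, v in cfg.joint_centers.items()},
        shank_marker=np.asarray(cfg.shank_marker, dtype=float),
        spring_constants=ks,
        natural_length_factor=float(cfg.natural_length_factor),
        reference_csa=float(cfg.reference_csa),
        reference_mass=float(cfg.reference_mass),
        csa_split={s: float(split[i]) for i, s in enumerate(PA_SLIPS)},
        heel_marker=cfg.heel_marker,
        toe_marker=cfg.toe_marker,
    )


# --------------------------------------------------------------------------
# Rigid pose fitting
# --------------------------------------------------------------------------

@dataclass
class RigidPose:
    """Proper rigid transform mapping segment-local to lab coordinates [mm].

    ``p_lab = rotation @ p_local + translation``.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass
class PoseSeries:
    """Per-frame rigid poses of one segment over a trial."""

    rotation: np.ndarray  # (F, 3, 3)
    translation: np.ndarray  # (F, 3)
    residual_rms: np.ndarray  # (F,)
    valid: np.ndarray  # (F,) bool

    @property
    def n_frames(self) -> int:
        return self.rotation.shape[0]

    def pose(self, i: int) -> RigidPose:
        return RigidPose(self.rotation[i], self.translation[i], float(self.residual_rms[i]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local ``(P, 3)`` points through every frame -> ``(F, P, 3)``."""
        pts = np.asarray(points, dtype=float)
        return np.einsum("fij,pj->fpi", self.rotation, pts) + self.translation[:, None, :]


def _kabsch(local_c: np.ndarray, obs_c: np.ndarray):
    """Proper rotation minimising ||R @ local - obs|| for centered point sets."""
    h = local_c.T @ obs_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def fit_segment_pose(local_markers: np.ndarray, observed: np.ndarray) -> RigidPose:
    """Least-squares rigid transform (orthogonal Procrustes) local -> lab.

    Parameters
    ----------
    local_markers, observed : (n, 3) arrays with n >= 3 corresponding,
        non-collinear markers.  A reflection-only optimum is corrected to a
        proper rotation.
    """
    local = np.asarray(local_markers, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if local.shape != obs.shape or local.ndim != 2 or local.shape[1] != 3:
        raise PoseError("local and observed marker arrays must both be (n, 3)")
    n = local.shape[0]
    if n < 3:
        raise PoseError(f"pose fitting needs >= 3 markers, got {n}")
    if _collinear(local):
        raise PoseError("local markers are collinear; pose is indeterminate")
    lc = local.mean(axis=0)
    oc = obs.mean(axis=0)
    rot = _kabsch(local - lc, obs - oc)
    t = oc - rot @ lc
    res = obs - (local @ rot.T + t)
    # per-coordinate RMS: under isotropic noise sigma its expectation is
    # sigma * sqrt(1 - 6/(3n)), the rigid-fit degrees-of-freedom count
    rms = float(np.sqrt(np.mean(res**2)))
    return RigidPose(rot, t, rms)


def fit_similarity(local_markers: np.ndarray, observed: np.ndarray):
    """Similarity fit (uniform scale + rigid) local -> lab.

    Returns ``(scale, RigidPose)`` where the pose applies to the *scaled*
    local coordinates.  The scale is the ratio of RMS centroid distances,
    which is exact for noise-free similar shapes and robust for small noise.
    """
    local = np.asarray(local_markers, dtype=float)
    obs = np.asarray(observed, dtype=float)
    lc = local - local.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    denom = np.sqrt(np.mean(np.sum(lc**2, axis=1)))
    if denom <= 0:
        raise PoseError("degenerate local markers (zero spread)")
    scale = float(np.sqrt(np.mean(np.sum(oc**2, axis=1))) / denom)
    pose = fit_segment_pose(local * scale, obs)
    return scale, pose


def fit_pose_series(local_markers: np.ndarray, observed: np.ndarray) -> PoseSeries:
    """Fit rigid poses frame by frame; frames with NaNs are flagged invalid."""
    obs = np.asarray(observed, dtype=float)  # (F, n, 3)
    nf = obs.shape[0]
    rot = np.full((nf, 3, 3), np.nan)
    tra = np.full((nf, 3), np.nan)
    rms = np.full(nf, np.nan)
    valid = np.zeros(nf, dtype=bool)
    for i in range(nf):
        if np.any(~np.isfinite(obs[i])):
            continue
        p = fit_segment_pose(local_markers, obs[i])
        rot[i] = p.rotation
        tra[i] = p.translation
        rms[i] = p.residual_rms
        valid[i] = True
    return PoseSeries(rot, tra, rms, valid)


# --------------------------------------------------------------------------
# Subject scaling
# --------------------------------------------------------------------------

@dataclass
class SubjectModel:
    """Template scaled to one subject from a quiet-standing trial."""

    template: FootTemplate
    subject_id: str
    body_mass: float  # kg
    segment_scale: dict  # segment -> uniform scale factor
    marker_local: dict  # label -> scaled local coords [mm]
    pa_paths: dict  # slip -> list of (segment, scaled local point)
    joint_centers: dict  # joint -> scaled neutral coords [mm]
    shank_marker: np.ndarray
    standing_poses: dict  # segment -> RigidPose in the standing trial
    foot_length: float  # m, heel-to-toe in standing
    standing_lengths: dict  # slip -> L_stand [mm]
    natural_lengths: dict  # slip -> L0 = c * L_stand [mm]
    csa: float  # subject PA cross-sectional area [mm^2]
    slip_csa: dict  # slip -> share of csa [mm^2]

    @property
    def spring_constants(self) -> dict:
        return self.template.spring_constants

    def segment_local_markers(self, segment: str) -> np.ndarray:
        return np.array(
            [self.marker_local[m] for m in self.template.segment_markers[segment]]
        )

    def to_json(self) -> str:
        payload = {
            "schema": "footspring.subject/1",
            "units": {"length": "mm", "mass": "kg", "stiffness": "N/mm", "csa": "mm^2"},
            "subject_id": self.subject_id,
            "body_mass": self.body_mass,
            "segment_scale": {k: float(v) for k, v in self.segment_scale.items()},
            "foot_length_m": self.foot_length,
            "standing_lengths": {k: float(v) for k, v in self.standing_lengths.items()},
            "natural_lengths": {k: float(v) for k, v in self.natural_lengths.items()},
            "csa": self.csa,
            "slip_csa": {k: float(v) for k, v in self.slip_csa.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def subject_csa(template: FootTemplate, body_mass: float) -> float:
    """Allometric PA cross-sectional area: A_ref * (m / m_ref)^(2/3) [mm^2]."""
    if body_mass <= 0:
        raise ScalingError("body mass must be positive")
    return template.reference_csa * (body_mass / template.reference_mass) ** (2.0 / 3.0)


def scale_to_subject(
    template: FootTemplate,
    standing,
    body_mass: float,
    subject_id: str = "subject",
    static_rms_tol: float = 3.0,
) -> SubjectModel:
    """Scale the template to a subject from a quiet-standing trial.

    Each segment gets a uniform (similarity) scale so its template markers
    match the time-averaged standing markers in a least-squares sense;
    three-marker segments under-determine anisotropic scaling, so anisotropic
    scaling is deliberately not attempted.  PA paths and joint centers scale
    with their host segment about the segment marker centroid.

    ``standing`` must expose ``markers`` (label -> (F, 3) mm) and
    ``marker_time``.  A marker whose positional RMS about its time mean
    exceeds ``static_rms_tol`` mm triggers a non-static warning (an RMS
    criterion, unlike a frame-to-frame speed, is insensitive to ordinary
    marker noise).
    """
    markers = standing.markers
    missing = [m for m in template.marker_labels if m not in markers]
    if missing:
        raise ScalingError(f"standing trial is missing markers: {missing}")

    mean_pos = {}
    for label in template.marker_labels:
        traj = np.asarray(markers[label], dtype=float)
        mean_pos[label] = traj.mean(axis=0)
        if traj.shape[0] > 1:
            rms = float(np.sqrt(np.mean(
                np.sum((traj - mean_pos[label]) ** 2, axis=1)
            )))
            if rms > static_rms_tol:
                warnings.warn(
                    f"standing trial: marker {label!r} wanders {rms:.1f} mm "
                    "RMS; trial may not be static",
                    stacklevel=2,
                )

    segment_scale = {}
    standing_poses = {}
    marker_local = {}
    for seg in SEGMENTS:
        labels = template.segment_markers[seg]
        local = np.array([template.marker_local[m] for m in labels])
        obs = np.array([mean_pos[m] for m in labels])
        scale, pose = fit_similarity(local, obs)
        segment_scale[seg] = scale
        standing_poses[seg] = pose
        for m in labels:
            marker_local[m] = template.marker_local[m] * scale

    # scale hosted geometry with its segment (scale acts about the origin of
    # the neutral frame, consistently with the scaled marker coordinates)
    pa_paths = {
        slip: [(seg, pt * segment_scale[seg]) for seg, pt in path]
        for slip, path in template.pa_paths.items()
    }
    joint_host = {"mtp": "forefoot", "midtarsal": "hindfoot", "ankle": "hindfoot"}
    joint_centers = {
        j: template.joint_centers[j] * segment_scale[joint_host[j]]
        for j in template.joint_centers
    }
    shank_marker = template.shank_marker * segment_scale["hindfoot"]

    heel = mean_pos[template.heel_marker]
    toe = mean_pos[template.toe_marker]
    foot_length = float(np.linalg.norm(toe - heel)) / 1000.0  # m
    if foot_length <= 0:
        raise ScalingError("foot length must be positive")

    standing_lengths = {}
    for slip, path in pa_paths.items():
        pts = np.array([standing_poses[seg].apply(pt[None, :])[0] for seg, pt in path])
        standing_lengths[slip] = float(
            np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        )
    c = template.natural_length_factor
    natural_lengths = {s: c * L for s, L in standing_lengths.items()}

    csa = subject_csa(template, body_mass)
    slip_csa = {s: csa * template.csa_split[s] for s in PA_SLIPS}

    return SubjectModel(
        template=template,
        subject_id=subject_id,
        body_mass=float(body_mass),
        segment_scale=segment_scale,
        marker_local=marker_local,
        pa_paths=pa_paths,
        joint_centers=joint_centers,
        shank_marker=shank_marker,
        standing_poses=standing_poses,
        foot_length=foot_length,
        standing_lengths=standing_lengths,
        natural_lengths=natural_lengths,
        csa=csa,
        slip_csa=slip_csa,
    )


# --------------------------------------------------------------------------
# PA path points through fitted poses
# --------------------------------------------------------------------------

def pa_path_points(model: SubjectModel, poses: dict) -> dict:
    """Map every PA path point through its host segment's pose per frame.

    Parameters
    ----------
    model : SubjectModel
    poses : mapping segment -> :class:`PoseSeries` (phalanx, forefoot,
        hindfoot required).

    Returns
    -------
    dict slip -> ``(F, P, 3)`` lab-frame point series [mm], order preserved
    origin -> insertion.  Frames where any host pose is invalid are NaN.
    """
    for seg in SEGMENTS:
        if seg not in poses:
            raise PoseError(f"missing pose series for segment {seg!r}")
    nf = poses["hindfoot"].n_frames
    ok = np.logical_and.reduce([poses[s].valid for s in SEGMENTS])
    out = {}
    for slip, path in model.pa_paths.items():
        pts = np.full((nf, len(path), 3), np.nan)
        for j, (seg, pt) in enumerate(path):
            pts[:, j, :] = poses[seg].apply(pt[None, :])[:, 0, :]
        pts[~ok] = np.nan
        out[slip] = pts
    return out
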
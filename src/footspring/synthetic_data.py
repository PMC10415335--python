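"""Synthetic standing and drop-jump trials with ground truth.

The generator is kinematics-first: joint-angle waveforms and the net
vertical ground reaction force (vGRF) are prescribed as C1 shape-preserving
Hermite interpolants through keypoints taken from the reported group means
of drop-jump cohorts (sex-specific presets), markers are synthesized by
forward kinematics of the template foot, and plate forces are prescribed
independently to match the two-peak drop-jump vGRF shape.  Full dynamic
consistency between the two is therefore approximate; it is asserted only
at the level of the net impulse (see docs/methods.md).

Timeline: a trial starts with ``lead_time`` seconds of free fall (the drop
from the platform), contact occurs at ``t = lead_time``, stance lasts
``stance_duration`` and the trial ends ``tail_time`` after toe-off.  Markers
are sampled at 100 Hz, plate channels at 1000 Hz, time bases aligned at 0.

Units follow the capture convention: markers in mm, forces in N, moments in
N·m, lab frame X anterior / Y left / Z up.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from . import kinematics
from .foot_model import PA_SLIPS, SEGMENTS, FootTemplate, build_default_template

__all__ = [
    "GRAVITY",
    "MARKER_RATE",
    "ANALOG_RATE",
    "Waveform",
    "make_waveform",
    "Subject",
    "Plate",
    "PlateSeries",
    "Trial",
    "TrialParams",
    "GroundTruth",
    "female_params",
    "male_params",
    "preset_params",
    "sample_params",
    "generate_standing_trial",
    "generate_drop_jump_trial",
]

GRAVITY = 9.81  # m/s^2
MARKER_RATE = 100.0  # Hz
ANALOG_RATE = 1000.0  # Hz


# --------------------------------------------------------------------------
# Waveforms
# --------------------------------------------------------------------------

class Waveform:
    """C1 piecewise-cubic Hermite interpolant, held constant outside its span."""

    def __init__(self, times, values, slopes):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.slopes = np.asarray(slopes, dtype=float)
        self._spline = CubicHermiteSpline(self.times, self.values, self.slopes)
        self._dspline = self._spline.derivative()

    def __call__(self, t):
        tc = np.clip(t, self.times[0], self.times[-1])
        return self._spline(tc)

    def derivative(self, t):
        tc = np.clip(t, self.times[0], self.times[-1])
        return self._dspline(tc)

    def integrate(self, a: float, b: float) -> float:
        return float(self._spline.integrate(a, b))

    def shift(self, dt: float) -> "Waveform":
        return Waveform(self.times + dt, self.values, self.slopes)


def make_waveform(keypoints) -> Waveform:
    """Build a waveform from ``(time, value[, derivative])`` keypoints.

    Slopes default to shape-preserving (PCHIP) estimates, so monotone
    keypoints give a monotone interpolant; where a derivative is supplied it
    is honoured exactly at that keypoint.  Times must be strictly
    increasing.
    """
    pts = []
    for kp in keypoints:
        if len(kp) == 2:
            t, v = kp
            s = None
        else:
            t, v, s = kp
        pts.append((float(t), float(v), None if s is None else float(s)))
    if len(pts) < 2:
        raise ValueError("need at least 2 keypoints")
    times = np.array([p[0] for p in pts])
    if np.any(np.diff(times) <= 0):
        raise ValueError("keypoint times must be strictly increasing (no duplicates)")
    values = np.array([p[1] for p in pts])
    slopes = PchipInterpolator(times, values).derivative()(times)
    for i, p in enumerate(pts):
        if p[2] is not None:
            slopes[i] = p[2]
    return Waveform(times, values, slopes)


# --------------------------------------------------------------------------
# Trial containers
# --------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    sex: str  # "female" | "male"
    body_mass: float  # kg


@dataclass
class Plate:
    """Force plate with rectangular corner geometry in lab mm."""

    plate_id: str
    corners: np.ndarray  # (4, 2) x/y

    def contains(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        xmin, ymin = self.corners.min(axis=0)
        xmax, ymax = self.corners.max(axis=0)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


@dataclass
class PlateSeries:
    plate: Plate
    force: np.ndarray  # (N, 3) N
    moment: np.ndarray  # (N, 3) N·m about plate center
    cop: np.ndarray  # (N, 2) lab mm (NaN where unloaded)


def _rects_overlap(a: np.ndarray, b: np.ndarray) -> bool:
    ax0, ay0 = a.min(axis=0)
    ax1, ay1 = a.max(axis=0)
    bx0, by0 = b.min(axis=0)
    bx1, by1 = b.max(axis=0)
    return (ax0 < bx1) and (bx0 < ax1) and (ay0 < by1) and (by0 < ay1)


@dataclass
class Trial:
    """Synchronized marker trajectories and per-plate force data."""

    subject: Subject
    marker_time: np.ndarray  # (F,) s
    markers: dict  # label -> (F, 3) mm
    analog_time: np.ndarray  # (N,) s
    plates: list  # [posterior, anterior] PlateSeries
    marker_rate: float = MARKER_RATE
    analog_rate: float = ANALOG_RATE

    def __post_init__(self):
        if abs(self.analog_rate - 10.0 * self.marker_rate) > 1e-9:
            raise ValueError("analog rate must be 10x the marker rate")
        if abs(self.marker_time[0] - self.analog_time[0]) > 1e-12:
            raise ValueError("marker and analog time bases must align at frame 0")
        for a, b in zip(self.plates, self.plates[1:]):
            if _rects_overlap(a.plate.corners, b.plate.corners):
                raise ValueError("force-plate polygons overlap")

    def net_vgrf(self) -> np.ndarray:
        """Net vertical GRF [N]: sum of the vertical components of all plates."""
        return np.sum([p.force[:, 2] for p in self.plates], axis=0)


# --------------------------------------------------------------------------
# Trial parameters and presets
# --------------------------------------------------------------------------

@dataclass
class TrialParams:
    """Everything that defines one synthetic drop-jump trial.

    Event offsets are relative: ``t_impact`` from contact, ``trough_t`` and
    ``second_peak_t`` from the impact peak.  GRF levels are in body weights
    (BW); angle keypoints are ``joint -> plane -> [(t rel contact, value
    deg, slope deg/s | None), ...]``.
    """

    sex: str
    body_mass: float  # kg
    stance_duration: float  # s
    t_impact: float  # s after contact
    impact_peak_bw: float
    trough_bw: float
    trough_t: float  # s after impact
    second_peak_bw: float
    second_peak_t: float  # s after impact (= T3 latency)
    contact_slope: float = 80.0  # BW/s, vGRF slope at contact
    toeoff_slope: float = -55.0  # BW/s, vGRF slope at toe-off
    angle_keypoints: dict = field(default_factory=dict)
    share_keypoints: list = field(default_factory=list)  # anterior-plate share
    cop_posterior: tuple = (-80.0, 0.0)  # lab mm
    cop_anterior: tuple = (78.0, 3.0)
    foot_origin: tuple = (-105.0, 0.0, 0.0)  # lab mm, heel-neutral offset
    marker_noise_mm: float = 0.5
    lead_time: float = 0.1  # s of free fall before contact
    tail_time: float = 0.1  # s after toe-off
    takeoff_velocity: float | None = None  # m/s; derived from impulse if None

    def validate(self) -> None:
        if self.stance_duration <= 0:
            raise ValueError("stance_duration must be positive")
        t2 = self.t_impact + self.trough_t
        t3 = self.t_impact + self.second_peak_t
        if not (0.0 < self.t_impact < t2 < t3 < self.stance_duration):
            raise ValueError(
                "event times must satisfy 0 < impact < trough < second peak < toe-off"
            )
        if not (self.impact_peak_bw > self.second_peak_bw > self.trough_bw > 0):
            raise ValueError(
                "drop-jump vGRF shape requires impact peak > second peak > trough > 0"
            )
        for joint, planes in self.angle_keypoints.items():
            for plane, kps in planes.items():
                times = [k[0] for k in kps]
                if any(b - a <= 0 for a, b in zip(times, times[1:])):
                    raise ValueError(f"{joint}/{plane} keypoint times not increasing")

    # -- derived event times, relative to contact
    @property
    def t2(self) -> float:
        return self.t_impact + self.trough_t

    @property
    def t3(self) -> float:
        return self.t_impact + self.second_peak_t

    @property
    def t4(self) -> float:
        return 0.5 * (self.t3 + self.stance_duration)

    def vgrf_waveform(self) -> Waveform:
        """Net vGRF in BW on the stance interval (time relative to contact)."""
        return make_waveform([
            (0.0, 0.0, self.contact_slope),
            (self.t_impact, self.impact_peak_bw, 0.0),
            (self.t2, self.trough_bw, 0.0),
            (self.t3, self.second_peak_bw, 0.0),
            (self.stance_duration, 0.0, self.toeoff_slope),
        ])

    def share_waveform(self) -> Waveform:
        kps = self.share_keypoints or [
            (0.0, 0.12),
            (self.t_impact, 0.25),
            (self.t2, 0.45),
            (self.t3, 0.62),
            (self.t4, 0.85),
            (self.stance_duration, 1.0),
        ]
        return make_waveform(kps)

    def angle_waveform(self, joint: str, plane: str) -> Waveform:
        return make_waveform(self.angle_keypoints[joint][plane])


def _angle_keypoints(k: dict, lead: float, tail: float) -> dict:
    """Assemble the per-joint sagittal/frontal keypoint tables from knobs."""
    toe = k["stance"]
    t_imp = k["t_imp"]
    t2 = t_imp + k["trough_t"]
    t3 = t_imp + k["t3"]
    t4 = 0.5 * (t3 + toe)
    end = toe + tail

    mt_t4 = k["mt_t3"] + k["mt_t4_rate"] * (t4 - t3) * 0.5
    mt_toe = mt_t4 + k["mt_t4_rate"] * (toe - t4) * 0.7
    ank_t4 = k["ank_t3"] + k["ank_t4_rate"] * (t4 - t3) * 0.5
    ank_toe = ank_t4 + k["ank_t4_rate"] * (toe - t4) * 0.6

    return {
        "midtarsal": {
            "sagittal": [
                (-lead, 0.0, 0.0),
                (0.0, k["mt_contact"], None),
                (t_imp, k["mt_imp"], 0.0),
                (t2, k["mt_t2"], k["mt_t2_rate"]),
                (t3, k["mt_t3"], 0.0),
                (t4, mt_t4, k["mt_t4_rate"]),
                (toe, mt_toe, k["mt_t4_rate"] * 0.3),
                (end, mt_toe - 3.0, 0.0),
            ],
            "frontal": [
                (-lead, 0.0, 0.0),
                (0.0, 0.0, None),
                (t2, k["mt_ev"], 0.0),
                (t3, k["mt_ev"], 0.0),
                (toe, -1.0, None),
                (end, -1.0, 0.0),
            ],
        },
        "mtp": {
            "sagittal": [
                (-lead, 0.0, 0.0),
                (0.0, 0.0, None),
                (t_imp, k["mtp_imp"], None),
                (t2, k["mtp_t2"], 0.0),
                (t3, k["mtp_t2"] + 2.0, None),
                (t4, k["mtp_toe"] * 0.25, None),
                (toe, k["mtp_toe"], k["mtp_toe_rate"]),
                (end, k["mtp_toe"] + 3.0, 0.0),
            ],
        },
        "ankle": {
            "sagittal": [
                (-lead, 0.0, 0.0),
                (0.0, 2.0, None),
                (t_imp, k["ank_imp"], None),
                (t2, k["ank_t2"], 0.0),
                (t3, k["ank_t3"], 0.0),
                (t4, ank_t4, k["ank_t4_rate"]),
                (toe, ank_toe, -150.0),
                (end, ank_toe - 3.0, 0.0),
            ],
        },
    }


# Sex-specific default knobs.  GRF levels, stance and event latencies, the
# T2/T3 midtarsal dorsiflexion, the T2 midtarsal dorsiflexion velocity, the
# toe-off MTP dorsiflexion and the T4 joint velocities are the printed
# female/male group means of the study cohort; the impact-peak offset is the
# unique value consistent with the printed stance/T3/T4 means; remaining
# knobs are unreported and set to realistic values (see docs/methods.md).
# mt_imp is chosen so the midtarsal angle acceleration is continuous at the
# velocity-constrained T2 knot: a C1-only Hermite corner there is an
# interpolation artifact, not physiology, and would alias into any
# finite-difference velocity estimate.
_FEMALE_KNOBS = dict(
    body_mass=55.1, stance=0.26, t_imp=0.054, trough_t=0.045, t3=0.078,
    impact=3.0, trough=1.6, second=2.8,
    mt_contact=4.0, mt_imp=8.26, mt_t2=11.4, mt_t2_rate=65.2, mt_t3=12.2,
    mt_t4_rate=-310.0, mt_ev=2.5,
    mtp_imp=-5.0, mtp_t2=-8.0, mtp_toe=17.1, mtp_toe_rate=120.0,
    ank_imp=8.0, ank_t2=12.0, ank_t3=13.0, ank_t4_rate=-240.0,
)
_MALE_KNOBS = dict(
    body_mass=59.6, stance=0.28, t_imp=0.049, trough_t=0.050, t3=0.099,
    impact=3.0, trough=1.4, second=2.6,
    mt_contact=3.0, mt_imp=7.0, mt_t2=7.1, mt_t2_rate=20.1, mt_t3=8.3,
    mt_t4_rate=-152.0, mt_ev=1.5,
    mtp_imp=-4.0, mtp_t2=-7.0, mtp_toe=7.9, mtp_toe_rate=100.0,
    ank_imp=7.0, ank_t2=10.0, ank_t3=11.0, ank_t4_rate=-372.0,
)

# Printed between-subject SDs used when sampling cohorts (same keys as the
# knob tables; knobs without a printed SD get a mild default jitter).
_FEMALE_SD = dict(
    body_mass=8.9, stance=0.02, t3=0.015, trough=0.2, impact=0.25,
    mt_t2=4.4, mt_t3=3.9, mt_t2_rate=45.2, mt_t4_rate=73.2, mtp_toe=6.9,
    ank_t4_rate=93.3,
)
_MALE_SD = dict(
    body_mass=6.1, stance=0.01, t3=0.019, trough=0.2, impact=0.25,
    mt_t2=4.2, mt_t3=3.9, mt_t2_rate=35.4, mt_t4_rate=129.0, mtp_toe=7.7,
    ank_t4_rate=141.0,
)


def _params_from_knobs(sex: str, knobs: dict, marker_noise_mm: float,
                       lead: float, tail: float) -> TrialParams:
    p = TrialParams(
        sex=sex,
        body_mass=knobs["body_mass"],
        stance_duration=knobs["stance"],
        t_impact=knobs["t_imp"],
        impact_peak_bw=knobs["impact"],
        trough_bw=knobs["trough"],
        trough_t=knobs["trough_t"],
        second_peak_bw=knobs["second"],
        second_peak_t=knobs["t3"],
        angle_keypoints=_angle_keypoints(knobs, lead, tail),
        marker_noise_mm=marker_noise_mm,
        lead_time=lead,
        tail_time=tail,
    )
    p.validate()
    return p


def female_params(marker_noise_mm: float = 0.5, lead_time: float = 0.1,
                  tail_time: float = 0.1, **knob_overrides) -> TrialParams:
    """Nominal female drop-jump trial parameters (group-mean keypoints)."""
    knobs = dict(_FEMALE_KNOBS, **knob_overrides)
    return _params_from_knobs("female", knobs, marker_noise_mm, lead_time, tail_time)


def male_params(marker_noise_mm: float = 0.5, lead_time: float = 0.1,
                tail_time: float = 0.1, **knob_overrides) -> TrialParams:
    """Nominal male drop-jump trial parameters (group-mean keypoints)."""
    knobs = dict(_MALE_KNOBS, **knob_overrides)
    return _params_from_knobs("male", knobs, marker_noise_mm, lead_time, tail_time)


def preset_params(sex: str, **kwargs) -> TrialParams:
    if sex == "female":
        return female_params(**kwargs)
    if sex == "male":
        return male_params(**kwargs)
    raise ValueError(f"unknown sex preset {sex!r}")


def sample_params(sex: str, rng: np.random.Generator,
                  marker_noise_mm: float = 0.5) -> TrialParams:
    """Draw one subject's trial parameters around the sex preset.

    Keypoints with printed between-subject SDs are perturbed with independent
    Gaussians at those SDs; other knobs get a 5% jitter.  Draws violating the
    event-ordering or GRF-shape constraints are resampled.
    """
    base = dict(_FEMALE_KNOBS if sex == "female" else _MALE_KNOBS)
    sds = _FEMALE_SD if sex == "female" else _MALE_SD
    for _ in range(100):
        knobs = {}
        for key, val in base.items():
            sd = sds.get(key, 0.05 * abs(val))
            knobs[key] = val + rng.normal(0.0, sd)
        knobs["body_mass"] = max(40.0, knobs["body_mass"])
        try:
            return _params_from_knobs(sex, knobs, marker_noise_mm, 0.1, 0.1)
        except ValueError:
            continue
    raise RuntimeError("could not sample valid trial parameters")


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------

_POSTERIOR_CORNERS = np.array([[-300.0, -250.0], [-300.0, 250.0],
                               [0.0, 250.0], [0.0, -250.0]])
_ANTERIOR_CORNERS = _POSTERIOR_CORNERS + np.array([300.0, 0.0])


def _plates() -> tuple:
    return (Plate("posterior", _POSTERIOR_CORNERS.copy()),
            Plate("anterior", _ANTERIOR_CORNERS.copy()))


@dataclass
class GroundTruth:
    """What the generator prescribed, for round-trip verification."""

    params: TrialParams
    t_contact: float
    t_impact: float
    t2: float
    t3: float
    t4: float
    t_toeoff: float
    impulse_bw_s: float  # integral of net vGRF over stance, BW·s
    v_in: float  # COM speed at contact, m/s (downward positive)
    v_out: float  # prescribed takeoff speed, m/s
    angle_waveforms: dict  # joint -> plane -> Waveform (absolute trial time)
    vgrf_waveform: Waveform  # BW, absolute trial time

    @property
    def delta_v(self) -> float:
        return self.v_in + self.v_out

    def events_json(self) -> dict:
        return {
            "t_contact": self.t_contact,
            "t_impact": self.t_impact,
            "t2": self.t2,
            "t3": self.t3,
            "t4": self.t4,
            "t_toeoff": self.t_toeoff,
            "v_in": self.v_in,
            "v_out": self.v_out,
        }


def _plate_series(plate: Plate, fz: np.ndarray, cop_xy: np.ndarray) -> PlateSeries:
    n = fz.shape[0]
    force = np.zeros((n, 3))
    force[:, 2] = fz
    center = plate.corners.mean(axis=0)
    cop = np.where(fz[:, None] > 0, cop_xy, np.nan)
    r = (cop_xy - center) / 1000.0  # m
    moment = np.zeros((n, 3))
    moment[:, 0] = r[:, 1] * fz
    moment[:, 1] = -r[:, 0] * fz
    return PlateSeries(plate, force, moment, cop)


def generate_standing_trial(template: FootTemplate, subject: Subject,
                            seed: int = 0, duration: float = 1.0,
                            marker_noise_mm: float = 0.0,
                            anterior_share: float = 0.0,
                            foot_origin=(-105.0, 0.0, 0.0)) -> Trial:
    """Quiet-standing trial: static markers, body weight on the plates.

    The anterior plate is unloaded by default (heel-dominant stance on the
    posterior plate); the vertical forces always sum to m·g exactly.
    """
    rng = np.random.default_rng(seed)
    nf = int(round(duration * MARKER_RATE)) + 1
    na = int(round(duration * ANALOG_RATE)) + 1
    marker_time = np.arange(nf) / MARKER_RATE
    analog_time = np.arange(na) / ANALOG_RATE
    origin = np.asarray(foot_origin, dtype=float)

    markers = {}
    for label, p in template.marker_local.items():
        pos = np.tile(p + origin, (nf, 1))
        if marker_noise_mm > 0:
            pos = pos + rng.normal(0.0, marker_noise_mm, size=pos.shape)
        markers[label] = pos
    shank = np.tile(template.shank_marker + origin, (nf, 1))
    if marker_noise_mm > 0:
        shank = shank + rng.normal(0.0, marker_noise_mm, size=shank.shape)
    markers["shank_axis"] = shank

    weight = subject.body_mass * GRAVITY
    post, ant = _plates()
    fz_ant = np.full(na, anterior_share * weight)
    fz_post = np.full(na, (1.0 - anterior_share) * weight)
    cop_post = np.tile(origin[:2] + np.array([40.0, 0.0]), (na, 1))
    cop_ant = np.tile(origin[:2] + np.array([180.0, 0.0]), (na, 1))
    plates = [_plate_series(post, fz_post, cop_post),
              _plate_series(ant, fz_ant, cop_ant)]
    return Trial(subject, marker_time, markers, analog_time, plates)


def generate_drop_jump_trial(template: FootTemplate, params: TrialParams,
                             seed: int = 0, subject_id: str = "S1"):
    """Synthesize one drop-jump trial.

    Returns ``(Trial, GroundTruth)``.  Segment poses follow the prescribed
    angle waveforms (rotations about the template joint centers), markers
    are the template markers mapped through those poses plus isotropic
    Gaussian noise, and the two plates split the prescribed net vGRF with
    the posterior plate carrying the impact-phase (heel) load.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    subject = Subject(subject_id, params.sex, params.body_mass)

    contact = params.lead_time
    toeoff = contact + params.stance_duration
    total = params.lead_time + params.stance_duration + params.tail_time
    nf = int(round(total * MARKER_RATE)) + 1
    na = int(round(total * ANALOG_RATE)) + 1
    marker_time = np.arange(nf) / MARKER_RATE
    analog_time = np.arange(na) / ANALOG_RATE

    # --- net vGRF and plate split -------------------------------------
    weight = params.body_mass * GRAVITY
    vgrf_bw = params.vgrf_waveform()
    share = params.share_waveform()
    ta = analog_time - contact
    in_stance = (ta >= 0.0) & (ta <= params.stance_duration)
    net_bw = np.where(in_stance, np.maximum(vgrf_bw(ta), 0.0), 0.0)
    a_share = np.clip(share(ta), 0.0, 1.0)
    fz_ant = a_share * net_bw * weight
    fz_post = (1.0 - a_share) * net_bw * weight

    post, ant = _plates()
    cop_post = np.tile(np.asarray(params.cop_posterior), (na, 1))
    cop_ant = np.tile(np.asarray(params.cop_anterior), (na, 1))
    plates = [_plate_series(post, fz_post, cop_post),
              _plate_series(ant, fz_ant, cop_ant)]

    # --- COM-velocity bookkeeping -------------------------------------
    impulse_bw_s = vgrf_bw.integrate(0.0, params.stance_duration)
    delta_v = (impulse_bw_s - params.stance_duration) * GRAVITY
    v_in = GRAVITY * params.lead_time
    v_out = params.takeoff_velocity
    if v_out is None:
        v_out = delta_v - v_in

    # --- segment poses -------------------------------------------------
    waves = {
        j: {pl: params.angle_waveform(j, pl).shift(contact)
            for pl in params.angle_keypoints[j]}
        for j in params.angle_keypoints
    }

    def plane(joint, name, t):
        if name in waves[joint]:
            return waves[joint][name](t)
        return np.zeros_like(t)

    mt_ang = np.stack([plane("midtarsal", p, marker_time)
                       for p in ("sagittal", "frontal", "transverse")], axis=1)
    mtp_ang = np.stack([plane("mtp", p, marker_time)
                        for p in ("sagittal", "frontal", "transverse")], axis=1)
    ank_ang = np.stack([plane("ankle", p, marker_time)
                        for p in ("sagittal", "frontal", "transverse")], axis=1)

    # vertical excursion of the foot: free fall before contact, flat during
    # stance, ballistic after toe-off
    z_off = np.zeros(nf)
    pre = marker_time < contact
    z_off[pre] = 0.5 * GRAVITY * (contact - marker_time[pre]) ** 2 * 1000.0
    post_air = marker_time > toeoff
    dt_post = marker_time[post_air] - toeoff
    z_off[post_air] = np.maximum(
        (v_out * dt_post - 0.5 * GRAVITY * dt_post**2) * 1000.0, 0.0
    )

    origin = np.asarray(params.foot_origin, dtype=float)
    c_mt = template.joint_centers["midtarsal"]
    c_mtp = template.joint_centers["mtp"]
    c_ank = template.joint_centers["ankle"]

    markers = {label: np.empty((nf, 3)) for label in template.marker_local}
    markers["shank_axis"] = np.empty((nf, 3))
    for i in range(nf):
        r_mt = kinematics.joint_rotation(*mt_ang[i])
        r_mtp = kinematics.joint_rotation(*mtp_ang[i])
        r_ank = kinematics.joint_rotation(*ank_ang[i])
        shift = origin + np.array([0.0, 0.0, z_off[i]])

        def hind(p):
            return p + shift

        def fore(p):
            return hind(r_mt @ (p - c_mt) + c_mt)

        def phal(p):
            return fore(r_mtp @ (p - c_mtp) + c_mtp)

        def shank(p):
            return hind(r_ank.T @ (p - c_ank) + c_ank)

        maps = {"hindfoot": hind, "forefoot": fore, "phalanx": phal}
        for seg in SEGMENTS:
            f = maps[seg]
            for label in template.segment_markers[seg]:
                markers[label][i] = f(template.marker_local[label])
        markers["shank_axis"][i] = shank(template.shank_marker)

    if params.marker_noise_mm > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, params.marker_noise_mm, size=markers[label].shape
            )

    trial = Trial(subject, marker_time, markers, analog_time, plates)
    truth = GroundTruth(
        params=copy.deepcopy(params),
        t_contact=contact,
        t_impact=contact + params.t_impact,
        t2=contact + params.t2,
        t3=contact + params.t3,
        t4=contact + params.t4,
        t_toeoff=toeoff,
        impulse_bw_s=impulse_bw_s,
        v_in=v_in,
        v_out=v_out,
        angle_waveforms=waves,
        vgrf_waveform=vgrf_bw.shift(contact),
    )
    return trial, truth
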
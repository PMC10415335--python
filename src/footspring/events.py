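"""vGRF event detection, time alignment and trial selection.

Stance is the longest episode where the net vGRF exceeds 2% of body weight;
crossing times are refined by linear interpolation between samples.  The
impact peak (heel contact) defines t = 0 for all aligned series, and the
remaining event times are T1 (midpoint contact -> impact peak), T2 (first
vGRF minimum after the impact peak), T3 (second vGRF peak, minimum COM
height) and T4 (midpoint T3 -> toe-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

GRAVITY = 9.81

__all__ = [
    "EventError",
    "EventTable",
    "SelectionResult",
    "detect_stance",
    "detect_impact_peak",
    "locate_timepoints",
    "select_trial",
]


class EventError(ValueError):
    """Event detection failed (no stance, or a non-biphasic vGRF profile)."""


@dataclass
class EventTable:
    """Detected event times in seconds, on the acquisition time base.

    ``aligned(t)`` maps acquisition time to impact-aligned time (impact peak
    at 0).  T1 and T4 are the midpoint definitions; landing phase =
    [contact, T3], jumping phase = [T3, toe-off].
    """

    t_contact: float
    t_impact: float
    t2: float
    t3: float
    t_toeoff: float
    impact_degraded: bool = False

    def __post_init__(self):
        order = (self.t_contact, self.t1, self.t_impact, self.t2, self.t3,
                 self.t4, self.t_toeoff)
        if not all(b > a for a, b in zip(order, order[1:])):
            raise EventError(f"event ordering violated: {order}")

    @property
    def t1(self) -> float:
        return 0.5 * (self.t_contact + self.t_impact)

    @property
    def t4(self) -> float:
        return 0.5 * (self.t3 + self.t_toeoff)

    @property
    def stance_duration(self) -> float:
        return self.t_toeoff - self.t_contact

    def aligned(self, t):
        return np.asarray(t) - self.t_impact

    def as_dict(self) -> dict:
        return {
            "t_contact": self.t_contact,
            "t1": self.t1,
            "t_impact": self.t_impact,
            "t2": self.t2,
            "t3": self.t3,
            "t4": self.t4,
            "t_toeoff": self.t_toeoff,
            "stance_duration": self.stance_duration,
            "impact_degraded": self.impact_degraded,
        }

    #: event label -> acquisition time, in reporting order
    def named_times(self) -> dict:
        return {
            "impact": self.t_impact,
            "T1": self.t1,
            "T2": self.t2,
            "T3": self.t3,
            "T4": self.t4,
            "toeoff": self.t_toeoff,
        }


def _crossing(time, y, i_lo, i_hi, level):
    """Linear-interpolated crossing time between two adjacent samples."""
    y0, y1 = y[i_lo], y[i_hi]
    if y1 == y0:
        return time[i_lo]
    frac = (level - y0) / (y1 - y0)
    return time[i_lo] + frac * (time[i_hi] - time[i_lo])


def detect_stance(time: np.ndarray, net_vgrf: np.ndarray, body_mass: float,
                  threshold_bw: float = 0.02):
    """Stance bounds from a 2%-BW threshold on the net vGRF.

    Returns ``(t_contact, t_toeoff)`` with sub-sample crossings by linear
    interpolation.  The longest supra-threshold episode is taken; raises
    :class:`EventError` when the signal never exceeds the threshold.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(net_vgrf, dtype=float)
    level = threshold_bw * body_mass * GRAVITY
    above = y > level
    if not np.any(above):
        raise EventError(f"net vGRF never exceeds {threshold_bw:.0%} BW")
    # contiguous episodes
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
    stops = np.r_[edges[above[edges]], len(y) - 1 if above[-1] else []].astype(int)
    lengths = time[stops] - time[starts]
    k = int(np.argmax(lengths))
    i0, i1 = starts[k], stops[k]
    t_on = _crossing(time, y, i0 - 1, i0, level) if i0 > 0 else time[i0]
    t_off = _crossing(time, y, i1, i1 + 1, level) if i1 < len(y) - 1 else time[i1]
    return t_on, t_off


def detect_impact_peak(time: np.ndarray, net_vgrf: np.ndarray, stance: tuple,
                       body_mass: float, min_peak_bw: float = 1.5):
    """First qualifying vGRF local maximum after contact.

    The qualifier (> ``min_peak_bw`` BW, within the first half of stance) is
    configurable; if no local maximum qualifies the global maximum of the
    first half of stance is returned with a degraded-mode flag.
    Returns ``(t_impact, degraded)``.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(net_vgrf, dtype=float)
    t_on, t_off = stance
    half = t_on + 0.5 * (t_off - t_on)
    mask = (time > t_on) & (time <= half)
    if not np.any(mask):
        raise EventError("stance window contains no samples")
    idx = np.flatnonzero(mask)
    w = y[idx]
    level = min_peak_bw * body_mass * GRAVITY
    peaks, _ = find_peaks(w, height=level)
    if len(peaks):
        return float(time[idx[peaks[0]]]), False
    return float(time[idx[np.argmax(w)]]), True


def locate_timepoints(time: np.ndarray, net_vgrf: np.ndarray, stance: tuple,
                      t_impact: float, impact_degraded: bool = False) -> EventTable:
    """Locate T2 (post-impact minimum) and T3 (second peak); build the table."""
    time = np.asarray(time, dtype=float)
    y = np.asarray(net_vgrf, dtype=float)
    t_on, t_off = stance
    mask = (time > t_impact) & (time < t_off)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise EventError("no samples between impact peak and toe-off")
    w = y[idx]
    mins, _ = find_peaks(-w)
    if not len(mins):
        raise EventError("non-biphasic vGRF: no local minimum after the impact peak (T2)")
    i2 = idx[mins[0]]
    t2 = float(time[i2])
    after = idx[idx > i2]
    if not len(after):
        raise EventError("non-biphasic vGRF: no samples after T2 for the second peak (T3)")
    i3 = after[np.argmax(y[after])]
    t3 = float(time[i3])
    if y[i3] <= y[i2]:
        raise EventError("non-biphasic vGRF: second peak (T3) not above the T2 minimum")
    return EventTable(t_contact=t_on, t_impact=float(t_impact), t2=t2, t3=t3,
                      t_toeoff=t_off, impact_degraded=impact_degraded)


# --------------------------------------------------------------------------
# Trial selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the trial-selection rules; accepted iff no reasons."""

    accepted: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted flag inconsistent with reasons")


def _marker_at(trial, label: str, t: float) -> np.ndarray:
    traj = np.asarray(trial.markers[label], dtype=float)
    return np.array([
        np.interp(t, trial.marker_time, traj[:, k]) for k in range(3)
    ])


def select_trial(trial, events: EventTable, model,
                 edge_tol_mm: float = 15.0,
                 contact_time_limit: float = 0.3,
                 heel_lift_tol_mm: float = 10.0,
                 plate_force_floor_n: float = 20.0) -> SelectionResult:
    """Apply the trial-selection rules.

    (i)   plate placement: navicular and fifth-metatarsal-base markers within
          ``edge_tol_mm`` of the inter-plate edge at heel contact;
    (ii)  heel contact: the heel marker descends to within
          ``heel_lift_tol_mm`` of its standing height while the posterior
          plate is loaded during the landing phase;
    (iii) contact time: stance duration below ``contact_time_limit``.
    """
    reasons = []

    # (i) plate placement at heel contact (impact peak ~ heel contact)
    post, ant = trial.plates[0].plate, trial.plates[1].plate
    edge_x = 0.5 * (post.corners[:, 0].max() + ant.corners[:, 0].min())
    for label in ("navicular", "mt5_base"):
        x = _marker_at(trial, label, events.t_impact)[0]
        if abs(x - edge_x) > edge_tol_mm:
            reasons.append("plate_placement")
            break

    # (ii) heel firmly on the ground while the posterior plate is loaded
    heel_local = model.marker_local[model.template.heel_marker]
    heel_stand = float(model.standing_poses["hindfoot"].apply(heel_local[None])[0, 2])
    landing = (trial.analog_time >= events.t_contact) & (trial.analog_time <= events.t3)
    loaded = landing & (trial.plates[0].force[:, 2] > plate_force_floor_n)
    if not np.any(loaded):
        reasons.append("heel_contact")
    else:
        heel_z = np.interp(trial.analog_time[loaded], trial.marker_time,
                           np.asarray(trial.markers[model.template.heel_marker])[:, 2])
        if float(np.min(heel_z)) > heel_stand + heel_lift_tol_mm:
            reasons.append("heel_contact")

    # (iii) contact time
    if events.stance_duration >= contact_time_limit:
        reasons.append("contact_time")

    return SelectionResult(accepted=not reasons, reasons=reasons)
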
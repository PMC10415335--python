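"""Plantar-aponeurosis slip mechanics: length, strain, tension, stress.

Each slip is a polyline through its origin, intermediate and insertion
points; its length is the summed Euclidean segment length.  Strain is
relative to the natural length L0 = 0.98 x the quiet-standing length, the
strain rate is the time derivative of the strain, tension is a tension-only
linear spring F = k * max(0, L - L0) (the slips cannot push), and stress is
tension over the slip's share of the subject's PA cross-sectional area
(MPa = N/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foot_model import PA_SLIPS, SubjectModel
from .kinematics import differentiate

__all__ = ["PASeries", "pa_lengths", "pa_strain", "pa_strain_rate",
           "pa_force_stress", "pa_series"]


@dataclass
class PASeries:
    """Per-slip PA time series on the kinematic (marker) time base."""

    time: np.ndarray
    length: dict  # slip -> (F,) mm
    strain: dict  # slip -> (F,) dimensionless
    strain_rate: dict  # slip -> (F,) 1/s
    tension: dict  # slip -> (F,) N
    stress: dict  # slip -> (F,) MPa


def pa_lengths(path_points: dict) -> dict:
    """Polyline length per slip and frame.

    ``path_points`` maps slip -> (F, P, 3) lab points [mm] (NaN frames
    propagate as NaN lengths).
    """
    out = {}
    for slip, pts in path_points.items():
        pts = np.asarray(pts, dtype=float)
        if pts.shape[1] < 3:
            raise ValueError(f"{slip}: path needs >= 3 points, got {pts.shape[1]}")
        seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
        out[slip] = seg.sum(axis=1)
    return out


def pa_strain(lengths: dict, model: SubjectModel) -> dict:
    """Engineering strain (L - L0) / L0 against the natural length."""
    out = {}
    for slip in PA_SLIPS:
        l0 = model.natural_lengths[slip]
        if l0 <= 0:
            raise ValueError(f"{slip}: natural length must be positive")
        out[slip] = (np.asarray(lengths[slip], dtype=float) - l0) / l0
    return out


def pa_strain_rate(strain: dict, timestep: float) -> dict:
    """Time derivative of the strain (shared central-difference operator)."""
    return {slip: differentiate(s, timestep) for slip, s in strain.items()}


def pa_force_stress(lengths: dict, model: SubjectModel):
    """Tension-only spring force [N] and stress [MPa] per slip.

    F = k * max(0, L - L0); sigma = F / A_slip with A_slip the slip's share
    of the subject's allometrically scaled PA cross-sectional area.
    """
    tension = {}
    stress = {}
    for slip in PA_SLIPS:
        k = model.spring_constants[slip]
        l0 = model.natural_lengths[slip]
        elong = np.maximum(0.0, np.asarray(lengths[slip], dtype=float) - l0)
        tension[slip] = k * elong
        stress[slip] = tension[slip] / model.slip_csa[slip]
    return tension, stress


def pa_series(path_points: dict, model: SubjectModel, time: np.ndarray) -> PASeries:
    """Full PA pipeline: lengths -> strain -> strain rate -> tension/stress."""
    time = np.asarray(time, dtype=float)
    dt = float(np.mean(np.diff(time)))
    lengths = pa_lengths(path_points)
    strain = pa_strain(lengths, model)
    rate = pa_strain_rate(strain, dt)
    tension, stress = pa_force_stress(lengths, model)
    return PASeries(time, lengths, strain, rate, tension, stress)
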
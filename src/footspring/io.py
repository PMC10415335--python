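"""Trial readers/writers, run configuration and the pipeline glue.

Trials are serialized as paired TSV files (markers: time + <label>_X/Y/Z in
mm at 100 Hz; plates: time, plate id, force N, moment N·m, COP mm at
1000 Hz) plus a small JSON meta file.  Every output embeds the resolved
config hash and package version as a provenance comment.  Output time
convention: seconds, t = 0 at the impact peak; raw trial files keep
acquisition time.  Lab frame: X anterior, Y left, Z up.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import dynamics, events, kinematics, pa_mechanics, stats
from .foot_model import (PA_SLIPS, SEGMENTS, SubjectModel, TemplateConfig,
                         build_default_template, pa_path_points, scale_to_subject)
from .synthetic_data import (ANALOG_RATE, GRAVITY, MARKER_RATE, Plate,
                             PlateSeries, Subject, Trial, generate_drop_jump_trial,
                             generate_standing_trial, sample_params)

__version__ = "0.1.0"

__all__ = [
    "RunConfig",
    "TrialResult",
    "PipelineResult",
    "write_trial",
    "read_trial",
    "process_trial",
    "run_pipeline",
    "simulate_cohort",
    "comparison_table",
]

EVENTS_REPORTED = ("impact", "T1", "T2", "T3", "T4", "toeoff")


class TrialParseError(ValueError):
    """Malformed trial file (reports the offending file and line)."""


@dataclass
class RunConfig:
    """Resolved analysis configuration; written beside every output."""

    filter_cutoff: float = 24.0  # Hz
    filter_order: int = 4
    stance_threshold_bw: float = 0.02
    impact_min_bw: float = 1.5
    contact_time_limit: float = 0.3  # s
    plate_edge_tol_mm: float = 15.0
    heel_lift_tol_mm: float = 10.0
    natural_length_factor: float = 0.98
    reference_csa: float = 69.2  # mm^2
    reference_mass: float = 70.0  # kg
    spring_constant: float = 40.0  # N/mm per slip
    euler_seq: str = kinematics.EULER_SEQ
    alpha: float = 0.05
    pa_alpha: float = 0.01  # 0.05 / 5
    foot_mass_fraction: float = 0.0137
    seed: int = 0

    def __post_init__(self):
        numeric = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                   if f.name not in ("euler_seq", "seed", "filter_order")}
        bad = [k for k, v in numeric.items() if not v > 0]
        if bad:
            raise ValueError(f"config fields must be positive: {bad}")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")

    def template_config(self) -> TemplateConfig:
        return TemplateConfig(
            spring_constant=self.spring_constant,
            natural_length_factor=self.natural_length_factor,
            reference_csa=self.reference_csa,
            reference_mass=self.reference_mass,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"# footspring v{__version__} config={config.hash}\n"


# --------------------------------------------------------------------------
# Trial TSV I/O
# --------------------------------------------------------------------------

def write_trial(trial: Trial, prefix) -> dict:
    """Write a trial as ``<prefix>_markers.tsv``, ``<prefix>_plates.tsv`` and
    ``<prefix>_meta.json``.  Deterministic and byte-stable for a fixed trial."""
    prefix = pathlib.Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": prefix.with_name(prefix.name + "_markers.tsv"),
        "plates": prefix.with_name(prefix.name + "_plates.tsv"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }

    labels = sorted(trial.markers)
    with open(paths["markers"], "w") as fh:
        fh.write("# markers [mm], lab frame: X anterior, Y left, Z up; time [s]\n")
        cols = ["time"] + [f"{m}_{ax}" for m in labels for ax in "XYZ"]
        fh.write("\t".join(cols) + "\n")
        for i, t in enumerate(trial.marker_time):
            row = [f"{t:.6f}"]
            for m in labels:
                row.extend(f"{v:.6f}" for v in trial.markers[m][i])
            fh.write("\t".join(row) + "\n")

    with open(paths["plates"], "w") as fh:
        fh.write("# plate wrenches: force [N], moment [N·m] about plate center, "
                 "COP [mm lab]; time [s]\n")
        fh.write("time\tplate\tFx\tFy\tFz\tMx\tMy\tMz\tCOPx\tCOPy\n")
        for ps in trial.plates:
            for i, t in enumerate(trial.analog_time):
                row = [f"{t:.6f}", ps.plate.plate_id]
                row.extend(f"{v:.6f}" for v in ps.force[i])
                row.extend(f"{v:.6f}" for v in ps.moment[i])
                row.extend("nan" if not np.isfinite(v) else f"{v:.6f}"
                           for v in ps.cop[i])
                fh.write("\t".join(row) + "\n")

    meta = {
        "schema": "footspring.trial/1",
        "subject": dataclasses.asdict(trial.subject),
        "marker_rate": trial.marker_rate,
        "analog_rate": trial.analog_rate,
        "plates": {ps.plate.plate_id: ps.plate.corners.tolist() for ps in trial.plates},
        "plate_order": [ps.plate.plate_id for ps in trial.plates],
    }
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_trial(prefix, required_markers=None) -> Trial:
    """Read a trial written by :func:`write_trial`.

    Validates rates, units alignment and marker completeness; a missing
    marker is reported by name (e.g. ``navicular``).
    """
    prefix = pathlib.Path(prefix)
    mpath = prefix.with_name(prefix.name + "_markers.tsv")
    ppath = prefix.with_name(prefix.name + "_plates.tsv")
    jpath = prefix.with_name(prefix.name + "_meta.json")
    for p in (mpath, ppath, jpath):
        if not p.exists():
            raise TrialParseError(f"missing trial file {p}")

    with open(jpath) as fh:
        meta = json.load(fh)
    subject = Subject(**meta["subject"])

    try:
        mdf = pd.read_csv(mpath, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas reports details
        raise TrialParseError(f"{mpath}: {exc}") from exc
    labels = sorted({c.rsplit("_", 1)[0] for c in mdf.columns if c != "time"})
    if required_markers is None:
        required_markers = [m for m in build_default_template().marker_labels]
        required_markers.append("shank_axis")
    missing = [m for m in required_markers if m not in labels]
    if missing:
        raise TrialParseError(f"{mpath}: missing marker(s) {missing}")
    markers = {}
    for m in labels:
        try:
            markers[m] = mdf[[f"{m}_X", f"{m}_Y", f"{m}_Z"]].to_numpy(dtype=float)
        except KeyError as exc:
            raise TrialParseError(f"{mpath}: marker {m!r} lacks X/Y/Z columns") from exc
    marker_time = mdf["time"].to_numpy(dtype=float)

    try:
        pdf = pd.read_csv(ppath, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover
        raise TrialParseError(f"{ppath}: {exc}") from exc
    plates = []
    analog_time = None
    for pid in meta["plate_order"]:
        sub = pdf[pdf["plate"] == pid]
        if sub.empty:
            raise TrialParseError(f"{ppath}: no rows for plate {pid!r}")
        t = sub["time"].to_numpy(dtype=float)
        if analog_time is None:
            analog_time = t
        plate = Plate(pid, np.asarray(meta["plates"][pid], dtype=float))
        plates.append(PlateSeries(
            plate,
            sub[["Fx", "Fy", "Fz"]].to_numpy(dtype=float),
            sub[["Mx", "My", "Mz"]].to_numpy(dtype=float),
            sub[["COPx", "COPy"]].to_numpy(dtype=float),
        ))
    return Trial(subject, marker_time, markers, analog_time, plates,
                 marker_rate=meta["marker_rate"], analog_rate=meta["analog_rate"])


# --------------------------------------------------------------------------
# Per-trial processing
# --------------------------------------------------------------------------

def _eval(time: np.ndarray, values: np.ndarray, t: float) -> float:
    """Cubic interpolation of a sampled series at one time point."""
    ok = np.isfinite(values)
    if ok.sum() < 4:
        return float("nan")
    return float(CubicSpline(time[ok], values[ok])(t))


@dataclass
class TrialResult:
    subject_id: str
    sex: str
    events: events.EventTable
    selection: events.SelectionResult
    angle_series: kinematics.JointAngleSeries
    velocity: dict  # joint -> (F, 3) deg/s
    kinetics: dynamics.JointKineticsSeries
    pa: pa_mechanics.PASeries
    scalars: dict  # parameter name -> value
    flagged_frames: dict = field(default_factory=dict)


def process_trial(model: SubjectModel, trial: Trial, config: RunConfig,
                  reference: dict | None = None) -> TrialResult:
    """Run one drop-jump trial through the full pipeline.

    Events are detected on the unfiltered 1000 Hz net vGRF; markers are
    low-pass filtered before pose fitting; joint kinematics, inverse
    dynamics, PA mechanics and the per-event scalar table all use the
    impact-aligned time base.
    """
    net = trial.net_vgrf()
    mass = trial.subject.body_mass
    stance = events.detect_stance(trial.analog_time, net, mass,
                                  config.stance_threshold_bw)
    t_imp, degraded = events.detect_impact_peak(trial.analog_time, net, stance,
                                                mass, config.impact_min_bw)
    table = events.locate_timepoints(trial.analog_time, net, stance, t_imp, degraded)

    filtered = {
        label: kinematics.lowpass_filter(traj, trial.marker_rate,
                                         config.filter_cutoff, config.filter_order)
        for label, traj in trial.markers.items()
    }
    poses = kinematics.fit_trial_poses(filtered, model)
    angle_series = kinematics.joint_angles(poses, trial.marker_time, reference)
    velocity = angle_series.velocity(trial.marker_rate)

    wrenches = dynamics.assign_plate_wrenches(trial)
    inertial = dynamics.default_inertial_params(model, config.foot_mass_fraction)
    kin = dynamics.inverse_dynamics(poses, wrenches, inertial, model,
                                    trial.marker_time)
    kin = dynamics.joint_power(kin, velocity)

    paths = pa_path_points(model, poses)
    pa = pa_mechanics.pa_series(paths, model, trial.marker_time)

    selection = events.select_trial(
        trial, table, model,
        edge_tol_mm=config.plate_edge_tol_mm,
        contact_time_limit=config.contact_time_limit,
        heel_lift_tol_mm=config.heel_lift_tol_mm,
    )

    scalars = _extract_scalars(trial, table, angle_series, velocity, kin, pa, model)
    flagged = {seg: wrenches[seg]["flagged"] for seg in SEGMENTS}
    return TrialResult(trial.subject.subject_id, trial.subject.sex, table,
                       selection, angle_series, velocity, kin, pa, scalars, flagged)


def _extract_scalars(trial, table, angle_series, velocity, kin, pa, model):
    mass = trial.subject.body_mass
    weight = mass * GRAVITY
    net = trial.net_vgrf()
    tm = trial.marker_time
    named = table.named_times()

    out = {
        "stance_duration_s": table.stance_duration,
        "t3_latency_ms": (table.t3 - table.t_impact) * 1000.0,
        "t4_latency_ms": (table.t4 - table.t_impact) * 1000.0,
        "impact_peak_bw": float(np.interp(table.t_impact, trial.analog_time, net)) / weight,
    }
    for ev, t in named.items():
        out[f"vgrf_bw@{ev}"] = float(np.interp(t, trial.analog_time, net)) / weight
    for joint in kinematics.JOINTS:
        ang = angle_series.angles[joint][:, 0]
        vel = velocity[joint][:, 0]
        mom = dynamics.normalize(kin.moment[joint][:, 0], "foot_moment",
                                 mass, model.foot_length).values
        pw = dynamics.normalize(kin.power[joint], "power", mass).values
        for ev, t in named.items():
            out[f"{joint}_sagittal_deg@{ev}"] = _eval(tm, ang, t)
            out[f"{joint}_sagittal_velocity_degs@{ev}"] = _eval(tm, vel, t)
            out[f"{joint}_moment_norm@{ev}"] = _eval(tm, mom, t)
            out[f"{joint}_power_wkg@{ev}"] = _eval(tm, pw, t)
    for slip in PA_SLIPS:
        for ev, t in named.items():
            out[f"{slip}_strain@{ev}"] = _eval(tm, pa.strain[slip], t)
            out[f"{slip}_strain_rate@{ev}"] = _eval(tm, pa.strain_rate[slip], t)
            out[f"{slip}_stress_mpa@{ev}"] = _eval(tm, pa.stress[slip], t)
    return out


# --------------------------------------------------------------------------
# Cohort pipeline
# --------------------------------------------------------------------------

@dataclass
class CohortRecord:
    subject_id: str
    sex: str
    standing: Trial
    jump: Trial


@dataclass
class PipelineResult:
    config: RunConfig
    trials: list  # accepted TrialResult
    rejected: dict  # subject_id -> reasons
    comparison: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = _provenance(self.config)
        with open(outdir / "config.json", "w") as fh:
            fh.write(self.config.to_json() + "\n")
        rows = []
        for tr in self.trials:
            row = {"subject": tr.subject_id, "sex": tr.sex,
                   "accepted": tr.selection.accepted}
            row.update(tr.events.as_dict())
            row.update(tr.scalars)
            rows.append(row)
        with open(outdir / "scalars.csv", "w") as fh:
            fh.write(prov)
            pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.9g")
        with open(outdir / "comparison.csv", "w") as fh:
            fh.write(prov)
            self.comparison.to_csv(fh, index=False, float_format="%.9g")
        with open(outdir / "comparison.json", "w") as fh:
            payload = {
                "provenance": {"version": __version__, "config": self.config.hash},
                "rejected": self.rejected,
                "comparisons": self.comparison.to_dict(orient="records"),
            }
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_cohort(n_female: int = 9, n_male: int = 10, seed: int = 0,
                    marker_noise_mm: float = 0.5,
                    config: RunConfig | None = None) -> list:
    """Generate a synthetic cohort: per subject a standing and a jump trial."""
    cfg = config or RunConfig(seed=seed)
    template = build_default_template(cfg.template_config())
    rng = np.random.default_rng(seed)
    records = []
    for sex, n in (("female", n_female), ("male", n_male)):
        for i in range(n):
            params = sample_params(sex, rng, marker_noise_mm=marker_noise_mm)
            sid = f"{sex[0].upper()}{i + 1:02d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            jump, _ = generate_drop_jump_trial(template, params,
                                               seed=sub_seed, subject_id=sid)
            standing = generate_standing_trial(
                template, Subject(sid, sex, params.body_mass),
                seed=sub_seed + 1, marker_noise_mm=marker_noise_mm,
            )
            records.append(CohortRecord(sid, sex, standing, jump))
    return records


def comparison_table(results: list, config: RunConfig) -> pd.DataFrame:
    """Female-vs-male comparison over every shared scalar parameter.

    PA strain/strain-rate/stress parameters form five-slip families per
    quantity and event and get the Bonferroni-adjusted decision alongside
    the per-test one.
    """
    females = [r for r in results if r.sex == "female"]
    males = [r for r in results if r.sex == "male"]
    if len(females) < 3 or len(males) < 3:
        raise ValueError("need at least 3 accepted trials per group to compare")
    params = sorted(set.intersection(*(set(r.scalars) for r in results)))
    rows = []
    for name in params:
        a = np.array([r.scalars[name] for r in females], dtype=float)
        b = np.array([r.scalars[name] for r in males], dtype=float)
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            continue
        event = name.split("@")[1] if "@" in name else None
        res = stats.compare_groups(a, b, alpha=config.alpha,
                                   parameter=name, event=event)
        rows.append({
            "parameter": name, "event": event,
            "female_mean": res.mean_a, "female_sd": res.sd_a, "n_female": res.n_a,
            "male_mean": res.mean_b, "male_sd": res.sd_b, "n_male": res.n_b,
            "test": res.test, "statistic": res.statistic, "p_value": res.p_value,
            "significant": res.significant,
        })
    df = pd.DataFrame(rows)

    # Bonferroni decision for the five-slip PA families
    df["pa_family"] = [
        p.split("_", 1)[1] if p.startswith("PA") else ""
        for p in df["parameter"]
    ]
    df["significant_bonferroni"] = pd.NA
    for fam, sub in df[df["pa_family"] != ""].groupby("pa_family"):
        if len(sub) == PA_SLIPS.__len__():
            decisions = stats.bonferroni_family(sub["p_value"].tolist(),
                                                alpha=config.alpha)
            df.loc[sub.index, "significant_bonferroni"] = decisions
    return df


def run_pipeline(config: RunConfig, cohort: list) -> PipelineResult:
    """Process a cohort end to end and compare the sexes.

    Deterministic for a fixed config and inputs.  Raises with the per-trial
    rejection reasons when a group ends up with no accepted trials.
    """
    if not cohort:
        raise ValueError("empty cohort: no trials to process")
    template = build_default_template(config.template_config())
    accepted = []
    rejected = {}
    for rec in cohort:
        model = scale_to_subject(template, rec.standing,
                                 rec.jump.subject.body_mass, rec.subject_id)
        reference = kinematics.standing_reference(model, rec.standing)
        result = process_trial(model, rec.jump, config, reference)
        if result.selection.accepted:
            accepted.append(result)
        else:
            rejected[rec.subject_id] = list(result.selection.reasons)
    for sex in ("female", "male"):
        if not any(r.sex == sex for r in accepted):
            raise ValueError(
                f"no accepted {sex} trials; rejections: {rejected}"
            )
    comparison = comparison_table(accepted, config)
    return PipelineResult(config, accepted, rejected, comparison)
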
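"""Synthetic study data with known ground truth.

The generator stands in for the study's recordings: it samples subjects from
the participant-group distributions, instantiates the twelve static tasks as
postures and hand loads, solves the model to obtain ground-truth muscle
forces and L5-S1 loads, and then emits what the laboratory would have
recorded during a 3-s static hold — quasi-constant posture channels, static
ground-reaction forces, and raw-EMG-like signals whose envelopes track the
model activities.

EMG synthesis: per site, a Gaussian carrier band-limited to 30-450 Hz is
scaled by ``activity x MVC amplitude`` and perturbed by white noise whose
standard deviation is a configured fraction of the signal amplitude; MVC
trials are generated at activity 1.  This is the minimal model that the
band-pass -> rectify -> low-pass -> MVC-normalize chain provably inverts.

All randomness flows from one integer seed through named substreams
(subject, task, channel), so identical seeds regenerate identical trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .anthropometry import ParameterSet, SubjectProfile
from .config import load_config
from .emg import SITES, predicted_site_activity
from .io import write_timeseries_csv
from .kinematics import Posture, RhythmCoefficients, TimeSeries
from .model import HandLoad, PosedModel, build_chain, pose_chain
from .recruitment import (
    JointLoads,
    RecruitmentSolution,
    assemble_problem,
    l5s1_loads,
    solve_recruitment,
)

TASK_IDS = tuple(f"T{i}" for i in range(1, 13))


@dataclass(frozen=True)
class TaskDefinition:
    """One of the twelve static load-handling tasks."""

    id: str
    description: str
    load_kind: str          # none | dumbbells | box
    load_mass: float
    unilateral: bool
    posture: Mapping[str, float]
    hands: Mapping[str, Any]

    def __post_init__(self) -> None:
        if self.id not in TASK_IDS:
            raise ValueError(f"unknown task id {self.id!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-noise amplitudes for the synthetic recordings."""

    tremor_deg: float = 0.2        # SD of postural tremor on angle channels
    tremor_m: float = 0.002        # SD of hand-position tremor
    grf_sd_n: float = 5.0          # SD of force-plate noise per plate
    emg_rel: float = 0.05          # noise SD as a fraction of signal amplitude

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(tremor_deg=0.0, tremor_m=0.0, grf_sd_n=0.0, emg_rel=0.0)


@dataclass
class SyntheticTrial:
    subject: SubjectProfile
    task: TaskDefinition
    variant: str
    posture: Posture
    hand_load: HandLoad
    posture_ts: TimeSeries
    grf_ts: TimeSeries
    emg_ts: TimeSeries
    mvc_trials: tuple[TimeSeries, ...]
    solution: RecruitmentSolution
    loads: JointLoads
    site_activities: dict[str, float]
    seed: int


def load_tasks(config: Any = None) -> dict[str, TaskDefinition]:
    cfg = load_config(config, "tasks.yaml")
    tasks = {}
    for tid, spec in cfg["tasks"].items():
        load = spec["load"]
        tasks[tid] = TaskDefinition(
            id=tid,
            description=spec.get("description", ""),
            load_kind=load["kind"],
            load_mass=float(load["mass"]),
            unilateral=bool(load.get("unilateral", False)),
            posture=dict(spec["posture"]),
            hands=dict(spec["hands"]),
        )
    missing = set(TASK_IDS) - set(tasks)
    if missing:
        raise ValueError(f"task config missing tasks {sorted(missing)}")
    return tasks


def load_rhythm(config: Any = None) -> RhythmCoefficients:
    cfg = load_config(config, "tasks.yaml")
    return RhythmCoefficients.from_config(cfg["rhythm"])


def sample_subjects(
    n: int, sex: str, seed: int, config: Any = None
) -> list[SubjectProfile]:
    """Draw subjects from the participant-group distributions (truncated
    normal, +/- 3 SD) for stature, mass and age."""
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if n < 0:
        raise ValueError("n must be non-negative")
    cfg = load_config(config, "parameters.yaml")
    pop = cfg["population"][sex]
    rng = np.random.default_rng([seed, 101 if sex == "male" else 202])
    subjects = []
    for _ in range(n):
        stature_cm = _truncnorm(rng, *pop["stature_cm"])
        mass_kg = _truncnorm(rng, *pop["mass_kg"])
        age = _truncnorm(rng, *pop["age_yr"])
        subjects.append(
            SubjectProfile(sex=sex, stature=stature_cm / 100.0, mass=mass_kg, age=age)
        )
    return subjects


def _truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    dist = sp_stats.truncnorm(-3.0, 3.0, loc=mean, scale=sd)
    return float(dist.ppf(rng.uniform(sp_stats.norm.cdf(-3), sp_stats.norm.cdf(3))))


def task_posture(
    task: TaskDefinition,
    subject: SubjectProfile,
    config: Any = None,
) -> tuple[Posture, HandLoad]:
    """Instantiate a task template for a subject: posture angles, stature-
    scaled hand targets, and the hand load."""
    cfg = load_config(config, "tasks.yaml")
    rhythm = RhythmCoefficients.from_config(cfg["rhythm"])
    p = task.posture
    pelvis = (
        float(p.get("pelvis_tilt", 0.0)),
        float(p.get("pelvis_lateral", 0.0)),
        float(p.get("pelvis_axial", 0.0)),
    )
    total = (
        float(p.get("flexion", 0.0)),
        float(p.get("lateral", 0.0)),
        float(p.get("axial", 0.0)),
    )
    hands_cfg = task.hands
    s = subject.stature
    if "explicit" in hands_cfg:
        positions = [tuple(np.asarray(h, dtype=float) * s) for h in hands_cfg["explicit"]]
    else:
        z = cfg["height_classes"][hands_cfg["height_class"]] * s
        x = float(hands_cfg["reach"]) * s
        y = float(hands_cfg["lateral"]) * s
        positions = [(x, y, z), (x, -y, z)]
    if task.unilateral:
        positions = [positions[-1]]  # favored (right) side by default

    posture = Posture.from_total(
        pelvis_angles=pelvis,
        trunk_pelvis=total,
        rhythm=rhythm,
        hand_positions=tuple(positions),
        arm_abduction=float(p.get("arm_abduction", 0.0)),
    )
    if task.load_kind == "none" or task.load_mass == 0:
        load = HandLoad(0.0, "bilateral_box", ())
    elif task.unilateral:
        load = HandLoad(task.load_mass, "unilateral", (positions[0],))
    else:
        attachment = (
            "bilateral_dumbbells" if task.load_kind == "dumbbells" else "bilateral_box"
        )
        load = HandLoad(task.load_mass, attachment, tuple(positions))
    return posture, load


def solve_task(
    subject: SubjectProfile,
    task: TaskDefinition,
    params: ParameterSet,
    geometry: Any = None,
    task_config: Any = None,
) -> tuple[PosedModel, RecruitmentSolution, JointLoads]:
    """Pose the model for a task and solve the recruitment problem."""
    posture, load = task_posture(task, subject, task_config)
    chain = build_chain(subject, params, geometry)
    posed = pose_chain(chain, posture, (load,) if load.mass > 0 else ())
    solution = solve_recruitment(assemble_problem(posed))
    return posed, solution, l5s1_loads(solution, posed)


def _band_limited_carrier(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian carrier band-limited to the EMG band."""
    raw = rng.standard_normal(n)
    sos = sp_signal.butter(4, band, btype="band", fs=rate, output="sos")
    carrier = sp_signal.sosfiltfilt(sos, raw)
    return carrier / max(np.std(carrier), 1e-12)


def synth_trial(
    subject: SubjectProfile,
    task: TaskDefinition,
    params: ParameterSet,
    seed: int,
    noise: NoiseConfig | None = None,
    geometry: Any = None,
    task_config: Any = None,
    emg_config: Any = None,
    subject_index: int = 0,
) -> SyntheticTrial:
    """Forward-generate one static trial with known ground truth."""
    noise = noise if noise is not None else NoiseConfig()
    emg_cfg = load_config(emg_config, "emg.yaml")
    task_cfg = load_config(task_config, "tasks.yaml")
    duration = float(task_cfg.get("hold_duration_s", 3.0))
    task_no = int(task.id[1:])

    try:
        posed, solution, loads = solve_task(
            subject, task, params, geometry, task_cfg
        )
    except Exception as exc:
        raise RuntimeError(
            f"task {task.id} infeasible for subject "
            f"({subject.sex}, {subject.mass:.1f} kg): {exc}"
        ) from exc
    posture, load = posed.posture, (posed.hand_loads[0] if posed.hand_loads else HandLoad(0.0, "bilateral_box", ()))
    site_activities = predicted_site_activity(solution, emg_cfg["sites"])

    # --- posture channels (200 Hz) -----------------------------------------
    rng_pose = np.random.default_rng([seed, subject_index, task_no, 1])
    rate_pose = 200.0
    n_pose = int(rate_pose * duration)
    labels = [
        "pelvis_flexion", "pelvis_lateral", "pelvis_axial",
        "trunk_flexion", "trunk_lateral", "trunk_axial",
    ]
    base_vals = list(posture.pelvis_angles) + list(posture.trunk_pelvis)
    for k, hand in enumerate(posture.hand_positions):
        labels += [f"hand{k}_x", f"hand{k}_y", f"hand{k}_z"]
        base_vals += list(hand)
    data = np.tile(np.asarray(base_vals), (n_pose, 1))
    tremor = np.concatenate(
        [
            np.full(6, noise.tremor_deg),
            np.full(3 * len(posture.hand_positions), noise.tremor_m),
        ]
    )
    data += rng_pose.standard_normal(data.shape) * tremor[np.newaxis, :]
    posture_ts = TimeSeries(data, rate_pose, tuple(labels))

    # --- ground reaction forces (1000 Hz) ----------------------------------
    rng_grf = np.random.default_rng([seed, subject_index, task_no, 2])
    rate_grf = 1000.0
    n_grf = int(rate_grf * duration)
    g = posed.chain.geometry["gravity"]
    total_weight = (subject.mass + load.mass) * g
    grf = np.column_stack(
        [
            total_weight / 2.0 + noise.grf_sd_n * rng_grf.standard_normal(n_grf),
            total_weight / 2.0 + noise.grf_sd_n * rng_grf.standard_normal(n_grf),
        ]
    )
    grf_ts = TimeSeries(grf, rate_grf, ("plate1_fz", "plate2_fz"))

    # --- raw EMG (2000 Hz) --------------------------------------------------
    rate_emg = float(emg_cfg["rate_hz"])
    band = tuple(emg_cfg["bandpass_hz"])
    amp = float(emg_cfg["carrier_amplitude_mv"])
    n_emg = int(rate_emg * duration)

    def synth_emg(activities: Mapping[str, float], stream: int) -> TimeSeries:
        rng = np.random.default_rng([seed, subject_index, task_no, 3, stream])
        cols = []
        for site in SITES:
            a = float(activities[site])
            carrier = _band_limited_carrier(rng, n_emg, rate_emg, band)
            noise_w = rng.standard_normal(n_emg)
            cols.append(a * amp * carrier + noise.emg_rel * a * amp * noise_w)
        return TimeSeries(np.column_stack(cols), rate_emg, SITES)

    emg_ts = synth_emg(site_activities, 0)
    mvc_activity = {site: 1.0 for site in SITES}
    mvc_trials = tuple(
        synth_emg(mvc_activity, 10 + k) for k in range(int(emg_cfg["mvc_trials"]))
    )

    return SyntheticTrial(
        subject=subject,
        task=task,
        variant=params.variant,
        posture=posture,
        hand_load=load,
        posture_ts=posture_ts,
        grf_ts=grf_ts,
        emg_ts=emg_ts,
        mvc_trials=mvc_trials,
        solution=solution,
        loads=loads,
        site_activities=site_activities,
        seed=seed,
    )


def write_trial(trial: SyntheticTrial, out_dir: str | Path) -> Path:
    """Persist a trial as plain-text files (CSV + JSON + YAML manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_timeseries_csv(trial.posture_ts, out / "posture.csv")
    write_timeseries_csv(trial.grf_ts, out / "grf.csv")
    write_timeseries_csv(trial.emg_ts, out / "emg.csv")
    for k, mvc in enumerate(trial.mvc_trials, start=1):
        write_timeseries_csv(mvc, out / f"mvc_{k}.csv")
    ground_truth = {
        "solution": trial.solution.to_dict(),
        "loads": {
            "compression_n": trial.loads.compression,
            "ap_shear_n": trial.loads.ap_shear,
            "ml_shear_n": trial.loads.ml_shear,
            "resultant_shear_n": trial.loads.resultant_shear,
            "compression_bw": trial.loads.compression_bw,
            "shear_bw": trial.loads.shear_bw,
        },
        "site_activities": trial.site_activities,
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    manifest = {
        "seed": trial.seed,
        "task": trial.task.id,
        "variant": trial.variant,
        "subject": {
            "sex": trial.subject.sex,
            "stature_m": trial.subject.stature,
            "mass_kg": trial.subject.mass,
            "age_yr": trial.subject.age,
        },
        "hand_load_kg": trial.hand_load.mass,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out
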
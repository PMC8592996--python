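"""Study battery, trial recovery pipeline, and group statistics.

``run_battery`` reproduces the study design: 10 male base-models, 10 female
base-models and 10 female-specific models, each simulated for the twelve
tasks (360 rows).  ``process_trial`` is the measurement-side pipeline that
recovers posture, loads and EMG activities from recorded (here: synthetic)
time series.  The t statistics and Pearson correlations are computed from
their closed-form definitions so the pipeline carries no hidden dependence
on a statistics backend's defaults; only the t distribution's CDF comes from
scipy.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .anthropometry import MUSCLES, SubjectProfile, make_parameter_set
from .config import load_config
from .emg import emg_envelope, mvc_peaks, pearson_r, predicted_site_activity
from .io import read_timeseries_csv
from .kinematics import (
    Posture,
    RhythmCoefficients,
    TimeSeries,
    static_phase_average,
    zero_lag_lowpass,
)
from .model import HandLoad, build_chain, pose_chain
from .recruitment import (
    InfeasibleRecruitmentError,
    assemble_problem,
    l5s1_loads,
    normalize_bw,
    solve_recruitment,
)
from .synth import (
    TaskDefinition,
    load_rhythm,
    load_tasks,
    sample_subjects,
    solve_task,
)

RESULT_COLUMNS = [
    "model_id",
    "sex",
    "variant",
    "task",
    "feasible",
    "compression_n",
    "ap_shear_n",
    "ml_shear_n",
    "resultant_shear_n",
    "compression_bw",
    "shear_bw",
] + [f"f_{m}_bw" for m in MUSCLES]


def run_battery(
    male_subjects: Sequence[SubjectProfile],
    female_subjects: Sequence[SubjectProfile],
    tasks: Mapping[str, TaskDefinition] | None = None,
    parameters: Any = None,
    geometry: Any = None,
    task_config: Any = None,
) -> pd.DataFrame:
    """Simulate every model x task combination.

    Male subjects run under ``male_base``; every female subject runs under
    both ``female_base`` and ``female_specific``, so the row count is
    (n_males + 2 n_females) x n_tasks.  Infeasible runs are flagged, not
    dropped.
    """
    tasks = tasks if tasks is not None else load_tasks(task_config)
    rows = []
    runs: list[tuple[str, SubjectProfile, str]] = []
    for i, subject in enumerate(male_subjects):
        runs.append((f"m{i + 1:02d}", subject, "male_base"))
    for i, subject in enumerate(female_subjects):
        runs.append((f"f{i + 1:02d}", subject, "female_base"))
    for i, subject in enumerate(female_subjects):
        runs.append((f"f{i + 1:02d}", subject, "female_specific"))

    for model_id, subject, variant in runs:
        params = make_parameter_set(variant, subject, parameters)
        for task_id, task in tasks.items():
            row: dict[str, Any] = {
                "model_id": model_id,
                "sex": subject.sex,
                "variant": variant,
                "task": task_id,
            }
            try:
                posed, solution, loads = solve_task(
                    subject, task, params, geometry, task_config
                )
            except (InfeasibleRecruitmentError, RuntimeError) as exc:
                row["feasible"] = False
                row["diagnostic"] = str(exc)
                rows.append(row)
                continue
            row["feasible"] = True
            row["residual_rel"] = solution.residual_rel
            row["compression_n"] = loads.compression
            row["ap_shear_n"] = loads.ap_shear
            row["ml_shear_n"] = loads.ml_shear
            row["resultant_shear_n"] = loads.resultant_shear
            row["compression_bw"] = loads.compression_bw
            row["shear_bw"] = loads.shear_bw
            for muscle in MUSCLES:
                total = sum(
                    f
                    for f, fas in zip(solution.forces, posed.chain.fascicles)
                    if fas.muscle == muscle
                )
                # average of the left and right side sums, as %BW
                row[f"f_{muscle}_bw"] = normalize_bw(total / 2.0, subject.mass)
            rows.append(row)
    return pd.DataFrame(rows)


def default_battery(
    seed: int,
    n_per_sex: int = 10,
    parameters: Any = None,
    geometry: Any = None,
    task_config: Any = None,
) -> pd.DataFrame:
    """The shipped synthetic battery: subjects sampled from the group
    distributions, all three variants, all twelve tasks."""
    males = sample_subjects(n_per_sex, "male", seed, parameters)
    females = sample_subjects(n_per_sex, "female", seed, parameters)
    return run_battery(
        males, females, parameters=parameters, geometry=geometry, task_config=task_config
    )


# ---------------------------------------------------------------------------
# Measurement-side pipeline (recovery from recorded time series)
# ---------------------------------------------------------------------------

def recover_posture(
    posture_ts: TimeSeries,
    rhythm: RhythmCoefficients,
    start: float = 0.0,
    duration: float = 3.0,
    cutoff_hz: float = 6.0,
) -> Posture:
    """Low-pass (6 Hz, zero lag), average the static hold, rebuild the posture."""
    filtered = zero_lag_lowpass(posture_ts, cutoff_hz)
    means = static_phase_average(filtered, start, duration)
    get = dict(zip(filtered.labels, means))
    hands = []
    k = 0
    while f"hand{k}_x" in get:
        hands.append((get[f"hand{k}_x"], get[f"hand{k}_y"], get[f"hand{k}_z"]))
        k += 1
    return Posture.from_total(
        pelvis_angles=(get["pelvis_flexion"], get["pelvis_lateral"], get["pelvis_axial"]),
        trunk_pelvis=(get["trunk_flexion"], get["trunk_lateral"], get["trunk_axial"]),
        rhythm=rhythm,
        hand_positions=tuple(hands),
    )


def grf_consistency(
    grf_ts: TimeSeries,
    expected_weight_n: float,
    start: float = 0.0,
    duration: float = 3.0,
    cutoff_hz: float = 20.0,
) -> float:
    """|mean vertical GRF sum - supported weight| (N) over the hold window."""
    filtered = zero_lag_lowpass(grf_ts, cutoff_hz)
    means = static_phase_average(filtered, start, duration)
    return float(abs(means.sum() - expected_weight_n))


@dataclass
class ProcessedTrial:
    posture: Posture
    loads: "Any"
    solution: "Any"
    measured_activity: dict[str, float]
    predicted_activity: dict[str, float]
    grf_gap_n: float


def process_trial(
    trial_dir: str | Path,
    subject: SubjectProfile,
    variant: str,
    hand_load: HandLoad,
    parameters: Any = None,
    geometry: Any = None,
    task_config: Any = None,
    emg_config: Any = None,
    duration: float = 3.0,
) -> ProcessedTrial:
    """Run the full measurement pipeline on one recorded (synthetic) trial."""
    trial_dir = Path(trial_dir)
    emg_cfg = load_config(emg_config, "emg.yaml")
    rhythm = load_rhythm(task_config)

    posture_ts = read_timeseries_csv(trial_dir / "posture.csv")
    posture = recover_posture(posture_ts, rhythm, duration=duration)

    params = make_parameter_set(variant, subject, parameters)
    chain = build_chain(subject, params, geometry)
    posed = pose_chain(chain, posture, (hand_load,) if hand_load.mass > 0 else ())
    solution = solve_recruitment(assemble_problem(posed))
    loads = l5s1_loads(solution, posed)

    grf_ts = read_timeseries_csv(trial_dir / "grf.csv")
    g = chain.geometry["gravity"]
    grf_gap = grf_consistency(
        grf_ts, (subject.mass + hand_load.mass) * g, duration=duration
    )

    mvc_files = sorted(trial_dir.glob("mvc_*.csv"))
    mvc_trials = [read_timeseries_csv(p) for p in mvc_files]
    peaks = mvc_peaks(
        mvc_trials,
        band=tuple(emg_cfg["bandpass_hz"]),
        envelope_cutoff=emg_cfg["envelope_cutoff_hz"],
        order=emg_cfg["filter_order"],
    )
    emg_ts = read_timeseries_csv(trial_dir / "emg.csv")
    envelope = emg_envelope(
        emg_ts,
        peaks,
        band=tuple(emg_cfg["bandpass_hz"]),
        envelope_cutoff=emg_cfg["envelope_cutoff_hz"],
        order=emg_cfg["filter_order"],
    )
    measured = dict(
        zip(envelope.labels, static_phase_average(envelope, 0.0, duration))
    )
    predicted = predicted_site_activity(solution, emg_cfg["sites"])
    return ProcessedTrial(
        posture=posture,
        loads=loads,
        solution=solution,
        measured_activity=measured,
        predicted_activity=predicted,
        grf_gap_n=grf_gap,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def unpaired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Student t with pooled variance, df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sp_stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sample t on the paired differences, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd <= 0:
        raise ValueError("difference variance is zero; t statistic undefined")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * sp_stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def _pct_diff(larger: float, smaller: float) -> dict[str, float]:
    """Percent difference under both denominator conventions."""
    return {
        "pct_of_smaller": 100.0 * (larger - smaller) / smaller,
        "pct_of_larger": 100.0 * (larger - smaller) / larger,
    }


@dataclass
class ComparisonReport:
    per_task: pd.DataFrame
    aggregate: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_task": self.per_task.to_dict(orient="records"),
            "aggregate": self.aggregate,
            "note": "no multiple-testing correction applied",
        }


def summarize_differences(table: pd.DataFrame) -> ComparisonReport:
    """Group comparisons: male vs female base (unpaired), female base vs
    female-specific (paired per subject), per task and across tasks.

    Percent differences are reported under both denominator conventions
    (relative to the smaller and to the larger group mean).  Across-task
    aggregates weight tasks equally.
    """
    ok = table[table["feasible"]]
    needed = {"male_base", "female_base", "female_specific"}
    if not needed.issubset(set(ok["variant"])):
        raise ValueError(f"result table must contain variants {sorted(needed)}")

    records = []
    for task, sub in ok.groupby("task", sort=False):
        male = sub[sub["variant"] == "male_base"].sort_values("model_id")
        fbase = sub[sub["variant"] == "female_base"].sort_values("model_id")
        fspec = sub[sub["variant"] == "female_specific"].sort_values("model_id")
        rec: dict[str, Any] = {"task": task}
        for metric in ("compression_n", "resultant_shear_n", "compression_bw", "shear_bw"):
            m, fb, fs = (
                male[metric].mean(),
                fbase[metric].mean(),
                fspec[metric].mean(),
            )
            rec[f"male_{metric}"] = m
            rec[f"female_base_{metric}"] = fb
            rec[f"female_specific_{metric}"] = fs
        try:
            t, p = unpaired_ttest(
                male["compression_n"].to_numpy(), fbase["compression_n"].to_numpy()
            )
            rec["male_vs_fbase_t"], rec["male_vs_fbase_p"] = t, p
        except ValueError:
            rec["male_vs_fbase_t"] = rec["male_vs_fbase_p"] = np.nan
        if list(fbase["model_id"]) == list(fspec["model_id"]) and len(fbase) >= 2:
            try:
                t, p = paired_ttest(
                    fbase["compression_n"].to_numpy(), fspec["compression_n"].to_numpy()
                )
                rec["fbase_vs_fspec_t"], rec["fbase_vs_fspec_p"] = t, p
            except ValueError:
                rec["fbase_vs_fspec_t"] = rec["fbase_vs_fspec_p"] = np.nan
        records.append(rec)
    per_task = pd.DataFrame(records)

    aggregate: dict[str, Any] = {}
    for metric in ("compression_n", "resultant_shear_n", "compression_bw", "shear_bw"):
        m = per_task[f"male_{metric}"].mean()
        fb = per_task[f"female_base_{metric}"].mean()
        fs = per_task[f"female_specific_{metric}"].mean()
        pair_mf = _pct_diff(max(m, fb), min(m, fb))
        aggregate[f"male_vs_female_base_{metric}"] = {
            "male_mean": m,
            "female_base_mean": fb,
            "larger": "male" if m >= fb else "female_base",
            **pair_mf,
        }
        aggregate[f"female_base_vs_specific_{metric}"] = {
            "female_base_mean": fb,
            "female_specific_mean": fs,
            "change_pct_of_base": 100.0 * (fs - fb) / fb,
        }
    return ComparisonReport(per_task=per_task, aggregate=aggregate)


def emg_correlation_table(
    measured: pd.DataFrame, predicted: pd.DataFrame, min_range: float = 1e-3
) -> pd.DataFrame:
    """Per-site Pearson correlation across the task battery.

    ``measured`` and ``predicted`` are site x task tables.  Sites whose
    predicted activity range is below ``min_range`` are reported with NaN:
    the correlation is undefined for a (near-)constant vector.
    """
    rows = []
    for site in measured.index:
        x = measured.loc[site].to_numpy(dtype=float)
        y = predicted.loc[site].to_numpy(dtype=float)
        if y.max() - y.min() < min_range or x.max() - x.min() < min_range * 1e-3:
            rows.append({"site": site, "r": np.nan, "p": np.nan, "defined": False})
            continue
        r, p = pearson_r(x, y)
        rows.append({"site": site, "r": r, "p": p, "defined": True})
    return pd.DataFrame(rows).set_index("site")
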
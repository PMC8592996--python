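"""Surface-EMG processing: band-pass, rectification, envelope, MVC
normalization, and comparison with model-predicted muscle activities.

The processing chain mirrors the study protocol: 30-450 Hz band-pass,
full-wave rectification, 3 Hz zero-lag low-pass, then division by the peak
of the identically processed maximal-voluntary-contraction (MVC) envelope.
Model-predicted activity at an electrode site is the mean force/strength
ratio of the fascicles mapped to that site.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import load_config
from .kinematics import TimeSeries, bandpass, zero_lag_lowpass
from .recruitment import RecruitmentSolution

SITES = (
    "mf_left", "mf_right",
    "les_left", "les_right",
    "tes_left", "tes_right",
    "eo_left", "eo_right",
    "io_left", "io_right",
    "ra_left", "ra_right",
)


def raw_envelope(
    raw: TimeSeries,
    band: tuple[float, float] = (30.0, 450.0),
    envelope_cutoff: float = 3.0,
    order: int = 2,
) -> TimeSeries:
    """Band-pass, rectify and low-pass without MVC normalization."""
    if raw.rate < 1000.0:
        raise ValueError("EMG must be sampled at >= 1000 Hz for the 30-450 Hz band")
    filtered = bandpass(raw, band[0], band[1], order=order)
    rectified = TimeSeries(np.abs(filtered.data), raw.rate, raw.labels)
    return zero_lag_lowpass(rectified, envelope_cutoff, order=order)


def emg_envelope(
    raw: TimeSeries,
    mvc_peak: Mapping[str, float],
    band: tuple[float, float] = (30.0, 450.0),
    envelope_cutoff: float = 3.0,
    order: int = 2,
) -> TimeSeries:
    """MVC-normalized linear envelope of a raw EMG recording."""
    env = raw_envelope(raw, band=band, envelope_cutoff=envelope_cutoff, order=order)
    peaks = np.array([mvc_peak[label] for label in raw.labels], dtype=float)
    if np.any(peaks <= 0):
        bad = [l for l, p in zip(raw.labels, peaks) if p <= 0]
        raise ValueError(f"MVC peaks must be positive; offending sites: {bad}")
    return TimeSeries(env.data / peaks[np.newaxis, :], raw.rate, raw.labels)


def mvc_peaks(trials: Sequence[TimeSeries], **kwargs) -> dict[str, float]:
    """Per-site maximum of the processed envelope over the MVC trials."""
    if not trials:
        raise ValueError("at least one MVC trial is required")
    peaks: dict[str, float] = {}
    for trial in trials:
        env = raw_envelope(trial, **kwargs)
        for i, label in enumerate(trial.labels):
            peaks[label] = max(peaks.get(label, 0.0), float(env.data[:, i].max()))
    return peaks


def predicted_site_activity(
    solution: RecruitmentSolution,
    mapping: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Mean predicted activity (force/strength) of the fascicles at each site."""
    if mapping is None:
        mapping = load_config(None, "emg.yaml")["sites"]
    activities: dict[str, float] = {}
    for site, fascicles in mapping.items():
        if not fascicles:
            raise ValueError(f"EMG site {site!r} maps to no fascicles")
        activities[site] = float(
            np.mean([solution.activity_of(name) for name in fascicles])
        )
    return activities


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd**2))
    sy = np.sqrt(np.sum(yd**2))
    if sx == 0 or sy == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)
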
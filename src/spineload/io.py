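"""Readers and writers for the plain-text interchange formats.

Time series travel as CSV with a one-line rate header (``# rate_hz: 200``)
followed by a channel-name header row.  Marker trajectories can also be read
from TRC (tab-delimited, millimetres, standard header block).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .kinematics import TimeSeries


def write_timeseries_csv(series: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# rate_hz: {series.rate:g}\n")
        writer = csv.writer(fh)
        writer.writerow(series.labels)
        for row in series.data:
            writer.writerow([f"{v:.9g}" for v in row])


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "rate" not in first:
            raise ValueError(f"{path}: missing '# rate_hz:' header line")
        rate = float(first.split(":", 1)[1])
        reader = csv.reader(fh)
        labels = tuple(next(reader))
        data = np.array([[float(v) for v in row] for row in reader if row])
    return TimeSeries(data, rate, labels)


def read_trc(path: str | Path) -> TimeSeries:
    """Read a TRC marker file into a TimeSeries (metres, labels ``marker_X`` ...)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path} is not a TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate = float(meta["DataRate"])
    units = meta.get("Units", "mm")
    to_m = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}[units]
    marker_names = [m for m in lines[3].split("\t")[2:] if m]
    labels = tuple(f"{m}_{ax}" for m in marker_names for ax in "XYZ")
    rows = []
    for line in lines[5:]:
        parts = line.split("\t")
        if len(parts) < 3 or not parts[0].strip():
            continue
        values = [float(v) if v.strip() else np.nan for v in parts[2 : 2 + len(labels)]]
        rows.append(values)
    data = np.asarray(rows, dtype=float) * to_m
    if np.isnan(data).any():
        raise ValueError(f"{path} contains gaps; fill markers before loading")
    return TimeSeries(data, rate, labels)
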
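"""Time-series filtering, static-hold extraction, and lumbar kinematics.

Filtering follows the study protocol: zero-lag (forward-backward) 2nd-order
Butterworth low-pass for marker/GRF channels, band-pass for EMG.  The total
trunk-pelvis rotation is decomposed as intrinsic flexion (about +Y, subject's
left) -> lateral bend (about +X, anterior) -> axial rotation (about +Z,
superior) and distributed over the six intervertebral joints by a lumbar
rhythm whose per-plane fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

JOINTS = ("T12L1", "L1L2", "L2L3", "L3L4", "L4L5", "L5S1")
PLANES = ("flexion", "lateral", "axial")
_EULER_SEQ = "YXZ"  # intrinsic: flexion, lateral bend, axial rotation


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel recording (frames x channels)."""

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a frames x channels matrix")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.data.shape[0] / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.labels.index(label)]


def zero_lag_lowpass(series: TimeSeries, cutoff: float, order: int = 2) -> TimeSeries:
    """Forward-backward Butterworth low-pass (zero phase shift).

    Two cascaded passes mean the amplitude gain at the cutoff frequency is
    (1/sqrt(2))^2 = 0.5, not -3 dB.
    """
    nyquist = series.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=series.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return TimeSeries(filtered, series.rate, series.labels)


def bandpass(series: TimeSeries, low: float, high: float, order: int = 2) -> TimeSeries:
    """Zero-lag Butterworth band-pass; rejects DC, preserves mid-band amplitude."""
    nyquist = series.rate / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for sampling rate {series.rate} Hz"
        )
    sos = signal.butter(order, (low, high), btype="band", fs=series.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return TimeSeries(filtered, series.rate, series.labels)


def static_phase_average(
    series: TimeSeries, start: float, duration: float = 3.0
) -> np.ndarray:
    """Per-channel mean over the static hold window [start, start+duration)."""
    if start < 0 or duration <= 0:
        raise ValueError("window start must be >= 0 and duration > 0")
    i0 = int(round(start * series.rate))
    i1 = int(round((start + duration) * series.rate))
    if i1 > series.data.shape[0]:
        raise ValueError(
            f"window [{start}, {start + duration}] s exceeds the "
            f"{series.duration:.3f} s recording"
        )
    return series.data[i0:i1].mean(axis=0)


def _check_rotation(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name} must be a 3x3 matrix")
    if not np.allclose(m @ m.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(m), 1.0, atol=1e-8
    ):
        raise ValueError(f"{name} is not a proper rotation (orthonormal, det +1)")
    return m


def euler_to_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix from (flexion, lateral, axial) intrinsic angles in degrees."""
    f, l, a = np.asarray(angles_deg, dtype=float)
    return Rotation.from_euler(_EULER_SEQ, [f, l, a], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix`; returns (flexion, lateral, axial) deg."""
    return Rotation.from_matrix(matrix).as_euler(_EULER_SEQ, degrees=True)


def trunk_pelvis_rotation(thorax_frame: np.ndarray, pelvis_frame: np.ndarray) -> np.ndarray:
    """Decompose the thorax orientation relative to the pelvis into
    (flexion, lateral bend, axial rotation) in degrees."""
    thorax = _check_rotation(thorax_frame, "thorax_frame")
    pelvis = _check_rotation(pelvis_frame, "pelvis_frame")
    relative = pelvis.T @ thorax
    return matrix_to_euler(relative)


@dataclass(frozen=True)
class RhythmCoefficients:
    """Share of the total trunk-pelvis rotation taken by each of the six
    lumbar joints (cranial T12-L1 first), one row per plane."""

    flexion: tuple[float, ...]
    lateral: tuple[float, ...]
    axial: tuple[float, ...]

    def __post_init__(self) -> None:
        for plane in PLANES:
            coeffs = np.asarray(getattr(self, plane), dtype=float)
            if coeffs.shape != (len(JOINTS),):
                raise ValueError(f"{plane} rhythm needs {len(JOINTS)} fractions")
            if np.any(coeffs < 0):
                raise ValueError(f"{plane} rhythm fractions must be non-negative")
            if abs(coeffs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{plane} rhythm fractions sum to {coeffs.sum()}, expected 1"
                )

    @classmethod
    def from_config(cls, cfg: dict) -> "RhythmCoefficients":
        return cls(
            flexion=tuple(cfg["flexion"]),
            lateral=tuple(cfg["lateral"]),
            axial=tuple(cfg["axial"]),
        )

    def matrix(self) -> np.ndarray:
        """(6 joints x 3 planes) coefficient matrix."""
        return np.column_stack(
            [np.asarray(getattr(self, plane), dtype=float) for plane in PLANES]
        )


def distribute_lumbar_rotation(
    total_deg: np.ndarray, coeffs: RhythmCoefficients
) -> np.ndarray:
    """Split the total (flexion, lateral, axial) rotation over the six joints.

    Returns a (6 joints x 3 planes) array whose per-plane column sums
    reproduce the total exactly.
    """
    total = np.asarray(total_deg, dtype=float)
    if total.shape != (3,):
        raise ValueError("total rotation must be three plane angles")
    return coeffs.matrix() * total[np.newaxis, :]


@dataclass(frozen=True)
class Posture:
    """One static posture: pelvis orientation, trunk-pelvis rotation and its
    per-joint distribution, plus world-frame hand targets (m)."""

    pelvis_angles: tuple[float, float, float]  # (tilt/flexion, lateral, axial) deg
    trunk_pelvis: tuple[float, float, float]   # total lumbar rotation, deg
    joint_rotations: np.ndarray                # (6 joints x 3 planes) deg
    hand_positions: tuple[tuple[float, float, float], ...] = ()
    arm_elevation: float = 0.0
    arm_abduction: float = 0.0

    def __post_init__(self) -> None:
        rotations = np.asarray(self.joint_rotations, dtype=float)
        if rotations.shape != (len(JOINTS), 3):
            raise ValueError("joint_rotations must be 6 joints x 3 planes")
        if not np.allclose(rotations.sum(axis=0), self.trunk_pelvis, atol=1e-9):
            raise ValueError(
                "per-plane joint rotations must sum to the trunk-pelvis total"
            )
        object.__setattr__(self, "joint_rotations", rotations)

    @classmethod
    def from_total(
        cls,
        pelvis_angles: tuple[float, float, float],
        trunk_pelvis: tuple[float, float, float],
        rhythm: RhythmCoefficients,
        hand_positions: tuple[tuple[float, float, float], ...] = (),
        arm_elevation: float = 0.0,
        arm_abduction: float = 0.0,
    ) -> "Posture":
        joint_rotations = distribute_lumbar_rotation(np.asarray(trunk_pelvis), rhythm)
        return cls(
            pelvis_angles=tuple(pelvis_angles),
            trunk_pelvis=tuple(trunk_pelvis),
            joint_rotations=joint_rotations,
            hand_positions=tuple(tuple(p) for p in hand_positions),
            arm_elevation=arm_elevation,
            arm_abduction=arm_abduction,
        )
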
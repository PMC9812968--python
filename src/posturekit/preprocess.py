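"""Gravity alignment and low-pass filtering.

Clothing-mounted sensors have an unknown orientation relative to the limb, so
each day's data are rotated to put the mean acceleration of a standing
calibration segment on the +z axis.  During quiet standing the only
acceleration is gravity and the limbs are assumed vertical, so this aligns
every sensor's z-axis with the vertical.  The rotation is the minimal one
taking the calibration mean onto z-hat: axis = cross(mean, z-hat), angle =
angle(mean, z-hat), assembled with Rodrigues' formula.

Signals are then low-pass filtered with a second-order Butterworth at 3 Hz,
run forwards and backwards (zero phase; the effective magnitude response is
the square of the single-pass response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import CalibrationError, MissingSensorError, PostureKitError
from .records import SensorRecording

Z_HAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class AlignmentRotation:
    """Per-sensor rotation taking the standing-calibration mean onto +z."""

    sensor_id: str
    matrix: np.ndarray
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise CalibrationError(f"{self.sensor_id}: rotation must be 3x3")
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9):
            raise CalibrationError(f"{self.sensor_id}: rotation is not orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-9):
            raise CalibrationError(f"{self.sensor_id}: determinant is not +1")


def rotation_to_vertical(mean_accel: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping ``mean_accel`` onto the +z axis.

    Degenerate cases: a vector already on +z gives the identity; a vector
    anti-parallel to +z is rotated by pi about the x-axis (any perpendicular
    axis would do; x is the fixed convention).
    """
    v = np.asarray(mean_accel, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise CalibrationError("calibration mean acceleration has near-zero magnitude")
    v = v / norm
    c = float(np.dot(v, Z_HAT))
    axis = np.cross(v, Z_HAT)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # pi about x-hat
    axis = axis / s
    angle = np.arctan2(s, c)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def estimate_alignment(
    recording: SensorRecording,
    standing_interval: tuple[float, float],
    min_duration_s: float = 1.0,
) -> dict[str, AlignmentRotation]:
    """Estimate the gravity-alignment rotation of every sensor.

    ``standing_interval`` must lie inside the recording and be at least
    ``min_duration_s`` long.
    """
    start_s, end_s = standing_interval
    if end_s - start_s < min_duration_s:
        raise CalibrationError(
            f"calibration interval [{start_s}, {end_s}) shorter than {min_duration_s} s"
        )
    i0, i1 = recording.index_range(start_s, end_s)
    if i1 - i0 < min_duration_s * recording.sample_rate:
        raise CalibrationError(
            f"calibration interval [{start_s}, {end_s}) lies outside the recording"
        )
    rotations = {}
    for sensor in recording.sensors:
        mean = recording.data[sensor][i0:i1].mean(axis=0)
        rotations[sensor] = AlignmentRotation(
            sensor_id=sensor,
            matrix=rotation_to_vertical(mean),
            interval=(start_s, end_s),
        )
    return rotations


def apply_alignment(
    recording: SensorRecording, rotations: dict[str, AlignmentRotation]
) -> SensorRecording:
    """Rotate every sample of every sensor into the gravity-aligned frame."""
    data = {}
    for sensor in recording.sensors:
        if sensor not in rotations:
            raise MissingSensorError(f"no alignment rotation for sensor {sensor!r}")
        rot = np.asarray(rotations[sensor].matrix)
        data[sensor] = recording.data[sensor] @ rot.T
    return recording.with_data(data)


def butterworth_sos(cutoff_hz: float, sample_rate: float, order: int = 2):
    if not 0 < cutoff_hz < sample_rate / 2:
        raise PostureKitError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {sample_rate / 2}) Hz"
        )
    return signal.butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")


def lowpass(
    recording: SensorRecording,
    cutoff_hz: float = 3.0,
    order: int = 2,
    min_duration_s: float = 1.0,
) -> SensorRecording:
    """Zero-phase Butterworth low-pass (forward-backward) of every channel.

    Segments shorter than ``min_duration_s`` are rejected: reflect-padding a
    handful of samples gives the filter nothing to warm up on.
    """
    if recording.duration_s < min_duration_s:
        raise PostureKitError(
            f"segment of {recording.duration_s:.2f} s is shorter than the "
            f"{min_duration_s} s filtering minimum"
        )
    sos = butterworth_sos(cutoff_hz, recording.sample_rate, order)
    data = {
        sensor: signal.sosfiltfilt(sos, arr, axis=0, padtype="odd")
        for sensor, arr in recording.data.items()
    }
    return recording.with_data(data)
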
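"""Sensor-to-vertical inclination angles from aligned acceleration.

With the z-axis gravity-aligned and the data in units of g, the inclination
of a sensor (hence of the limb segment it rides on) is

    theta_z = arccos(s_z / g)                       (arccos estimator)

where ``s_z`` is the 1 s moving mean of the vertical acceleration component
and ``g`` is the magnitude of the moving-mean acceleration during quiet
standing (~1 in g-normalised data).  The arccos estimator returns 0-180
degrees and cannot distinguish forward from backward lean; the signed

    theta_z = atan2(s_y, s_z)                       (atan2 estimator)

can, but assumes the sensor y-axis stays in the sagittal plane, which a
sensor on loose clothing does not guarantee — it is provided for
completeness and is not used by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, PostureKitError
from .records import SensorRecording


@dataclass(frozen=True)
class GravityMagnitude:
    """|g| estimated from a standing segment, in g."""

    value: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise CalibrationError("gravity magnitude must be positive")


def moving_mean(values: np.ndarray, window_s: float, sample_rate: float) -> np.ndarray:
    """Centred moving average; edges are truncated to the available samples.

    Works on 1-D series or (n, k) arrays (column-wise).
    """
    if window_s <= 0:
        raise PostureKitError("window_s must be > 0")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise PostureKitError("cannot take a moving mean of an empty series")
    n = max(int(round(window_s * sample_rate)), 1)
    df = pd.DataFrame(values)
    out = df.rolling(n, center=True, min_periods=1).mean().to_numpy()
    return out[:, 0] if values.ndim == 1 else out


def smooth_recording(
    recording: SensorRecording, window_s: float = 1.0
) -> SensorRecording:
    """Recording with every channel replaced by its centred moving mean."""
    data = {
        sensor: moving_mean(arr, window_s, recording.sample_rate)
        for sensor, arr in recording.data.items()
    }
    return recording.with_data(data)


def estimate_gravity_magnitude(
    recording: SensorRecording,
    standing_interval: tuple[float, float],
    window_s: float = 1.0,
) -> dict[str, GravityMagnitude]:
    """Per-sensor |g|: mean norm of the moving-mean acceleration while standing."""
    start_s, end_s = standing_interval
    i0, i1 = recording.index_range(start_s, end_s)
    if i1 <= i0:
        raise CalibrationError(
            f"standing interval [{start_s}, {end_s}) lies outside the recording"
        )
    # smooth within the extracted interval so adjacent activities cannot leak
    # into the calibration windows
    segment = recording.slice_interval(start_s, end_s)
    out = {}
    for sensor in recording.sensors:
        smoothed = moving_mean(segment.data[sensor], window_s, segment.sample_rate)
        norms = np.linalg.norm(smoothed, axis=1)
        value = float(norms.mean())
        if value <= 1e-9:
            raise CalibrationError(
                f"standing interval has near-zero acceleration for sensor {sensor!r}"
            )
        out[sensor] = GravityMagnitude(value=value, interval=(start_s, end_s))
    return out


def inclination_arccos(sz: np.ndarray, g: GravityMagnitude | float) -> np.ndarray:
    """Inclination in degrees, [0, 180], from the vertical component.

    The ratio ``s_z / g`` is clamped to [-1, 1]: measurement noise can push
    the smoothed component slightly past the calibration magnitude.
    """
    gval = g.value if isinstance(g, GravityMagnitude) else float(g)
    if not gval > 0:
        raise CalibrationError("gravity magnitude must be positive")
    ratio = np.clip(np.asarray(sz, dtype=float) / gval, -1.0, 1.0)
    return np.degrees(np.arccos(ratio))


def inclination_atan2(sy: np.ndarray, sz: np.ndarray) -> np.ndarray:
    """Signed inclination in degrees, (-180, 180]; NaN where both inputs are 0."""
    sy = np.asarray(sy, dtype=float)
    sz = np.asarray(sz, dtype=float)
    out = np.degrees(np.arctan2(sy, sz))
    undefined = (sy == 0) & (sz == 0)
    if np.any(undefined):
        out = np.where(undefined, np.nan, out)
    return out
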
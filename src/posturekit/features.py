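"""Windowed variability features separating static postures from movement.

The static/dynamic discriminator is the moving standard deviation of
acceleration over a short window: during a held posture the accelerometer
sees gravity plus sensor noise (std well under 0.005 g), while walking or
stair climbing keeps it above 0.1 g.  Three candidate channels are used, all
on gravity-aligned, low-pass-filtered data: the thigh magnitude, the thigh
vertical (z) component, and the waist magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PostureKitError
from .records import SensorRecording

#: Candidate window sizes, seconds.
CANDIDATE_WINDOWS_S = (0.5, 1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class FeatureSeries:
    """A named dense feature series (one value per sample)."""

    name: str
    window_s: float
    time: np.ndarray
    values: np.ndarray


def magnitude(recording: SensorRecording, sensor_id: str) -> np.ndarray:
    """Per-sample Euclidean norm of a sensor's acceleration, in g."""
    return np.linalg.norm(recording.get(sensor_id), axis=1)


def moving_std(values: np.ndarray, window_s: float, sample_rate: float) -> np.ndarray:
    """Centred moving sample standard deviation (ddof=1), edges truncated.

    The stride is one sample, so the output stays aligned with the input
    series and with any per-sample annotations.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise PostureKitError("moving_std needs at least 2 samples")
    n = int(round(window_s * sample_rate))
    if n < 2:
        raise PostureKitError(
            f"window of {window_s} s is under 2 samples at {sample_rate} Hz"
        )
    out = (
        pd.Series(values).rolling(n, center=True, min_periods=2).std(ddof=1).to_numpy()
    )
    # only length-1 inputs could produce NaN, and those were rejected above
    return out


def interior_mask(n_samples: int, window_s: float, sample_rate: float) -> np.ndarray:
    """True where a centred window lies fully inside the series."""
    # pandas centred windows cover [i - n//2, i + (n-1)//2]
    n = int(round(window_s * sample_rate))
    left = n // 2
    right = (n - 1) // 2
    mask = np.zeros(n_samples, dtype=bool)
    if n_samples > left + right:
        mask[left : n_samples - right] = True
    return mask
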
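"""In-memory containers for accelerometer streams and labelled intervals.

A :class:`SensorRecording` holds one participant-day of triaxial acceleration,
in units of g, for a set of named sensor positions that share a uniform 50 Hz
time base.  An :class:`AnnotationTrack` is an ordered set of half-open labelled
intervals ``[start_s, end_s)`` on that same time axis; sample ``i`` (at time
``i / sample_rate``) belongs to the interval containing its timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, MissingSensorError

#: Default lower-body sensor positions (right trouser leg).
LOWER_BODY_SENSORS = ("waist", "thigh", "ankle")

#: Sampling rate of the sensor string, Hz.
SAMPLE_RATE = 50.0


@dataclass(frozen=True)
class Interval:
    """Half-open labelled time interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SensorRecording:
    """Synchronised triaxial acceleration streams for named sensor positions.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (50 for the sensor string emulated here).
    time : ndarray, shape (n,)
        Sample timestamps in seconds, uniformly spaced at ``1/sample_rate``.
    data : dict of str -> ndarray, shape (n, 3)
        Acceleration in g per sensor position, columns ``(x, y, z)``.
    """

    sample_rate: float
    time: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for sensor, arr in list(self.data.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise FormatError(
                    f"sensor {sensor!r}: expected shape ({n}, 3), got {arr.shape}"
                )
            self.data[sensor] = arr

    @property
    def sensors(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def get(self, sensor: str) -> np.ndarray:
        try:
            return self.data[sensor]
        except KeyError:
            raise MissingSensorError(
                f"sensor {sensor!r} not in recording (has {sorted(self.data)})"
            ) from None

    def require(self, sensors) -> None:
        missing = [s for s in sensors if s not in self.data]
        if missing:
            raise MissingSensorError(f"recording lacks sensors {missing}")

    def index_range(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Sample indices covered by the half-open interval ``[start_s, end_s)``."""
        fs = self.sample_rate
        i0 = int(np.ceil(start_s * fs - 1e-9))
        i1 = int(np.ceil(end_s * fs - 1e-9))
        offset = int(round(self.time[0] * fs))
        return max(i0 - offset, 0), min(i1 - offset, self.n_samples)

    def slice_interval(self, start_s: float, end_s: float) -> "SensorRecording":
        """Sub-recording over ``[start_s, end_s)``; timestamps are preserved."""
        i0, i1 = self.index_range(start_s, end_s)
        return SensorRecording(
            sample_rate=self.sample_rate,
            time=self.time[i0:i1].copy(),
            data={s: a[i0:i1].copy() for s, a in self.data.items()},
        )

    def with_data(self, data: dict[str, np.ndarray]) -> "SensorRecording":
        return SensorRecording(self.sample_rate, self.time.copy(), data)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns time_s, sensor_id, ax_g, ay_g, az_g."""
        parts = []
        for sensor in self.sensors:
            arr = self.data[sensor]
            parts.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "sensor_id": sensor,
                        "ax_g": arr[:, 0],
                        "ay_g": arr[:, 1],
                        "az_g": arr[:, 2],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


@dataclass
class AnnotationTrack:
    """Ordered labelled half-open intervals on a recording's time axis."""

    intervals: list[Interval] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def start_s(self) -> float:
        return self.intervals[0].start_s if self.intervals else 0.0

    @property
    def end_s(self) -> float:
        return self.intervals[-1].end_s if self.intervals else 0.0

    def duration_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)

    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.label, None)
        return tuple(seen)

    def select(self, labels) -> "AnnotationTrack":
        labels = set(labels)
        return AnnotationTrack([iv for iv in self.intervals if iv.label in labels])

    def first(self, label: str) -> Interval:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        raise KeyError(f"no interval labelled {label!r}")

    def validate_partition(self, tol: float = 1e-9) -> None:
        """Check intervals are sorted, non-overlapping and gap-free."""
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start_s - a.end_s > tol:
                raise FormatError(f"gap between {a} and {b}")
            if a.end_s - b.start_s > tol:
                raise FormatError(f"overlap between {a} and {b}")
        for iv in self.intervals:
            if iv.duration_s <= 0:
                raise FormatError(f"non-positive interval {iv}")

    def check_no_overlap(self, tol: float = 1e-9) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.end_s - b.start_s > tol:
                raise FormatError(f"overlapping intervals {a} and {b}")

    def sample_labels(self, time: np.ndarray, fill: str = "") -> np.ndarray:
        """Label of the interval containing each timestamp (half-open)."""
        time = np.asarray(time, dtype=float)
        out = np.full(time.shape, fill, dtype=object)
        for iv in self.intervals:
            mask = (time >= iv.start_s - 1e-9) & (time < iv.end_s - 1e-9)
            out[mask] = iv.label
        return out

    @classmethod
    def from_samples(
        cls, time: np.ndarray, labels: np.ndarray, sample_rate: float
    ) -> "AnnotationTrack":
        """Merge runs of equal per-sample labels into intervals.

        The final interval is closed at one sample period past the last
        timestamp, so the track tiles the recording exactly.
        """
        time = np.asarray(time, dtype=float)
        labels = np.asarray(labels, dtype=object)
        if time.size == 0:
            return cls([])
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [time.size]))
        dt = 1.0 / sample_rate
        intervals = [
            Interval(time[i0], time[i1 - 1] + dt, str(labels[i0]))
            for i0, i1 in zip(starts, ends)
        ]
        return cls(intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [iv.start_s for iv in self.intervals],
                "end_s": [iv.end_s for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )
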
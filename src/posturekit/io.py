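"""Plain-text tabular formats for recordings, annotations, rotations, models.

Everything round-trips through delimited text so artifacts stay reviewable:

* recordings: CSV with columns ``time_s, sensor_id, ax_g, ay_g, az_g``
  (seconds and g, 6-decimal fixed point);
* annotations: CSV with ``start_s, end_s, label`` (half-open intervals);
* alignment rotations: YAML with the 9 matrix entries and source interval;
* KNN models: CSV of features+label plus a YAML sidecar of hyperparameters;
* pipeline configuration: a flat YAML mapping.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import KnnModel, knn_fit
from .errors import FormatError
from .preprocess import AlignmentRotation
from .records import AnnotationTrack, Interval, SensorRecording

RECORDING_COLUMNS = ["time_s", "sensor_id", "ax_g", "ay_g", "az_g"]
ANNOTATION_COLUMNS = ["start_s", "end_s", "label"]


@dataclass
class PipelineConfig:
    """Tunable pipeline constants; defaults are the study's stated values."""

    sample_rate: float = 50.0
    filter_cutoff_hz: float = 3.0
    filter_order: int = 2
    classifier1_window_s: float = 3.0
    mean_window_s: float = 1.0
    knn_k: int = 10
    calibration_label: str = "standing"
    seed: int = 0
    sensors: tuple[str, ...] = ("waist", "thigh", "ankle")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sensors"] = list(d["sensors"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sensors" in d:
            d["sensors"] = tuple(d["sensors"])
        return cls(**d)


def write_recording(recording: SensorRecording, path) -> None:
    df = recording.to_frame()
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path, rate_tol: float = 1e-4) -> SensorRecording:
    """Parse a tabular sensor log, validating the schema and time base."""
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    sensors = list(dict.fromkeys(df["sensor_id"]))
    time = None
    data = {}
    for sensor in sensors:
        sub = df[df["sensor_id"] == sensor]
        t = sub["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise FormatError(f"{path}: sensor {sensor!r} has fewer than 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(sub.index[1:][dt <= 0][0]) + 2  # +header +0-base
            raise FormatError(f"{path}: non-monotone time at line {row}")
        if np.any(np.abs(dt - dt[0]) > rate_tol):
            row = int(sub.index[1:][np.abs(dt - dt[0]) > rate_tol][0]) + 2
            raise FormatError(f"{path}: inconsistent sampling interval at line {row}")
        if time is None:
            time = t
        elif t.size != time.size or np.any(np.abs(t - time) > rate_tol):
            raise FormatError(f"{path}: sensor {sensor!r} is not on the shared time base")
        data[sensor] = sub[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if time is None:
        raise FormatError(f"{path}: no samples")
    sample_rate = 1.0 / float(np.median(np.diff(time)))
    return SensorRecording(sample_rate=round(sample_rate, 6), time=time, data=data)


def write_annotations(track: AnnotationTrack, path) -> None:
    track.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_annotations(path) -> AnnotationTrack:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    intervals = [
        Interval(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    ]
    for i, iv in enumerate(intervals):
        if iv.duration_s <= 0:
            raise FormatError(f"{path}: non-positive interval at line {i + 2}")
    return AnnotationTrack(intervals)


def write_rotations(rotations: dict[str, AlignmentRotation], path) -> None:
    doc = {
        sensor: {
            "interval": list(rot.interval),
            "matrix": np.asarray(rot.matrix).reshape(-1).tolist(),
        }
        for sensor, rot in rotations.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_rotations(path) -> dict[str, AlignmentRotation]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for sensor, entry in doc.items():
        matrix = np.asarray(entry["matrix"], dtype=float).reshape(3, 3)
        out[sensor] = AlignmentRotation(
            sensor_id=sensor, matrix=matrix, interval=tuple(entry["interval"])
        )
    return out


def save_model(model: KnnModel, path) -> None:
    """Serialise a KNN model: CSV of rows+label, YAML sidecar of metadata."""
    path = Path(path)
    df = pd.DataFrame(model.X, columns=list(model.feature_names))
    df["label"] = model.y
    df.to_csv(path, index=False)
    meta = {
        "k": int(model.k),
        "metric": "euclidean",
        "weighting": "inverse_squared_distance",
        "feature_names": list(model.feature_names),
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def load_model(path) -> KnnModel:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
    df = pd.read_csv(path)
    names = meta["feature_names"]
    missing = [c for c in names + ["label"] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: model file missing columns {missing}")
    return knn_fit(
        df[names].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=object),
        k=int(meta["k"]),
        feature_names=tuple(names),
    )
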
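"""End-to-end assembly: from simulated days to trained, evaluated classifiers.

Training datasets are built per extracted activity segment: each annotated
interval is sliced out of the aligned recording, filtered, and windowed on
its own, mirroring ground-truth segments that were cut from the middle of
longer activity bouts (transitions between activities never contaminate a
training window).  Deployment-style prediction (`classify.cascade_predict`)
instead filters and windows the continuous stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    C1_FEATURES,
    DYNAMIC,
    STATIC,
    classifier1_features,
    classifier2_features,
)
from .inclination import GravityMagnitude, estimate_gravity_magnitude
from .preprocess import AlignmentRotation, apply_alignment, estimate_alignment, lowpass
from .records import AnnotationTrack, SensorRecording
from .synthetic import BenchmarkDay, DYNAMIC_LABELS, STANDING, STATIC_LABELS


@dataclass
class PreparedDay:
    """One day after gravity alignment and calibration."""

    aligned: SensorRecording
    annotations: AnnotationTrack
    participant: str
    rotations: dict[str, AlignmentRotation]
    gravity: dict[str, GravityMagnitude]


def prepare_day(
    recording: SensorRecording,
    annotations: AnnotationTrack,
    participant: str = "P1",
    calibration_label: str = STANDING,
    calibration_interval: tuple[float, float] | None = None,
) -> PreparedDay:
    """Align a day to gravity using its (first) standing interval.

    The calibration segment defaults to the first annotated standing
    interval; pass ``calibration_interval`` to override.
    """
    if calibration_interval is None:
        iv = annotations.first(calibration_label)
        calibration_interval = (iv.start_s, iv.end_s)
    rotations = estimate_alignment(recording, calibration_interval)
    aligned = apply_alignment(recording, rotations)
    gravity = estimate_gravity_magnitude(aligned, calibration_interval)
    return PreparedDay(
        aligned=aligned,
        annotations=annotations,
        participant=participant,
        rotations=rotations,
        gravity=gravity,
    )


def prepare_benchmark(days: list[BenchmarkDay]) -> list[PreparedDay]:
    return [
        prepare_day(d.recording, d.annotations, participant=d.participant) for d in days
    ]


def static_dynamic_dataset(
    prepared: list[PreparedDay],
    window_s: float = 3.0,
    feature_set: tuple[str, ...] = C1_FEATURES[:1],
    static_labels=STATIC_LABELS,
    dynamic_labels=DYNAMIC_LABELS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample Classifier-1 training set over all extracted segments.

    Returns (X, y, groups): moving-std features, static/dynamic labels and
    participant ids, one row per labelled sample.
    """
    static_labels = set(static_labels)
    dynamic_labels = set(dynamic_labels)
    Xs, ys, gs = [], [], []
    for day in prepared:
        for iv in day.annotations:
            if iv.label in static_labels:
                target = STATIC
            elif iv.label in dynamic_labels:
                target = DYNAMIC
            else:
                continue
            segment = lowpass(day.aligned.slice_interval(iv.start_s, iv.end_s))
            X = classifier1_features(segment, window_s=window_s, feature_set=feature_set)
            Xs.append(X)
            ys.append(np.full(len(X), target, dtype=object))
            gs.append(np.full(len(X), day.participant, dtype=object))
    return np.vstack(Xs), np.concatenate(ys), np.concatenate(gs)


def posture_dataset(
    prepared: list[PreparedDay],
    window_s: float = 1.0,
    sensors: tuple[str, ...] = ("waist", "thigh", "ankle"),
    static_labels=STATIC_LABELS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample Classifier-2 training set: inclination angles of static segments.

    Returns (X, y, groups) with one row per static sample; columns are the
    waist/thigh/ankle inclination angles in degrees.
    """
    static_labels = set(static_labels)
    Xs, ys, gs = [], [], []
    for day in prepared:
        for iv in day.annotations:
            if iv.label not in static_labels:
                continue
            segment = lowpass(day.aligned.slice_interval(iv.start_s, iv.end_s))
            X = classifier2_features(segment, g=day.gravity, window_s=window_s, sensors=sensors)
            Xs.append(X)
            ys.append(np.full(len(X), iv.label, dtype=object))
            gs.append(np.full(len(X), day.participant, dtype=object))
    return np.vstack(Xs), np.concatenate(ys), np.concatenate(gs)
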
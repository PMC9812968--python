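"""Synthetic clothing-mounted accelerometer recordings with known ground truth.

The generator emulates the study conditions the classifiers rely on:

* four static postures, each defined by a per-sensor inclination angle (the
  angle between the sensor z-axis and gravity), with between-repetition
  jitter — these produce the four separated clusters in waist/thigh/ankle
  angle space;
* two dynamic activities (walking, stairs) that add an oscillatory
  acceleration and sweep the inclination angle, so windowed variability is
  high wherever the wearer moves;
* an unknown per-day mount rotation for every sensor — clothing-mounted
  sensors have no fixed orientation relative to the limb, which is exactly
  what the standing-segment gravity calibration has to undo;
* white measurement noise small enough that static moving standard deviation
  stays below ~0.005 g while dynamic segments exceed 0.1 g.

Inclination is realised as a rotation about the sensor x-axis (sagittal-plane
motion): a sensor at inclination theta measures gravity ``(0, sin θ, cos θ)``
in g before the mount rotation is applied.  Only the z-component (hence θ_z)
is consumed downstream, so one rotation plane suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ProtocolError
from .records import LOWER_BODY_SENSORS, SAMPLE_RATE, AnnotationTrack, Interval, SensorRecording

STANDING = "standing"
SITTING = "sitting"
LYING = "lying"
LEGS_OUTSTRETCHED = "legs_outstretched"
WALKING = "walking"
STAIRS = "stairs"

STATIC_LABELS = (STANDING, SITTING, LYING, LEGS_OUTSTRETCHED)
DYNAMIC_LABELS = (WALKING, STAIRS)


@dataclass(frozen=True)
class PostureSpec:
    """A static posture archetype: one mean inclination angle per sensor.

    ``jitter_sd`` is the between-repetition dispersion of the realised angle
    (degrees): each time the posture is adopted the limb lands a little
    differently.
    """

    label: str
    angles: Mapping[str, float]
    jitter_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ProtocolError(f"{self.label}: jitter_sd must be >= 0")
        for sensor, angle in self.angles.items():
            if not 0.0 <= angle <= 180.0:
                raise ProtocolError(
                    f"{self.label}: angle for {sensor!r} must lie in [0, 180], got {angle}"
                )


@dataclass(frozen=True)
class DynamicSpec:
    """A dynamic activity: oscillatory acceleration plus an angle sweep."""

    label: str
    osc_amplitude: float = 0.3  # g
    osc_freq: float = 2.0  # Hz
    angle_sweep: float = 40.0  # degrees, peak-to-peak excursion

    def __post_init__(self) -> None:
        if self.osc_amplitude <= 0:
            raise ProtocolError(f"{self.label}: osc_amplitude must be > 0")
        if not 0.0 < self.osc_freq < SAMPLE_RATE / 2:
            raise ProtocolError(
                f"{self.label}: osc_freq must lie in (0, {SAMPLE_RATE / 2}) Hz"
            )


@dataclass(frozen=True)
class MountModel:
    """Unknown clothing-mount orientation of every sensor for one day.

    ``wobble_sd`` (degrees) is a small per-segment re-seating of the garment:
    each time the wearer changes activity the sensor settles at a slightly
    different angle.  It is constant within a segment so static windows stay
    static.
    """

    rotations: Mapping[str, np.ndarray]
    wobble_sd: float = 0.5

    def __post_init__(self) -> None:
        for sensor, rot in self.rotations.items():
            rot = np.asarray(rot, dtype=float)
            if rot.shape != (3, 3):
                raise ProtocolError(f"mount for {sensor!r} is not 3x3")
            if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
                raise ProtocolError(f"mount for {sensor!r} is not orthonormal")
            if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
                raise ProtocolError(f"mount for {sensor!r} has determinant != +1")

    @classmethod
    def identity(cls, sensors: Iterable[str] = LOWER_BODY_SENSORS, wobble_sd: float = 0.0):
        return cls({s: np.eye(3) for s in sensors}, wobble_sd=wobble_sd)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        sensors: Iterable[str] = LOWER_BODY_SENSORS,
        wobble_sd: float = 0.5,
    ) -> "MountModel":
        """Uniformly random orientation per sensor (fresh clothing fit)."""
        rots = {s: Rotation.random(rng=rng).as_matrix() for s in sensors}
        return cls(rots, wobble_sd=wobble_sd)


@dataclass(frozen=True)
class DayProtocol:
    """Ordered (label, duration_s) segments for one participant-day."""

    segments: tuple[tuple[str, float], ...]
    participant: str = "P1"
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.sample_rate != SAMPLE_RATE:
            raise ProtocolError(f"sample_rate is fixed at {SAMPLE_RATE} Hz")
        for label, dur in self.segments:
            if dur <= 0:
                raise ProtocolError(f"segment {label!r} has non-positive duration")

    def duration_s(self) -> float:
        return sum(d for _, d in self.segments)


# Default posture table (degrees, waist/thigh/ankle).  Chosen to give four
# well-separated clusters in angle space, with the sitting-vs-outstretched
# contrast carried mostly by the ankle; configurable, not ground truth for any
# real wearer.
DEFAULT_POSTURES: dict[str, PostureSpec] = {
    STANDING: PostureSpec(STANDING, {"waist": 5.0, "thigh": 5.0, "ankle": 5.0}),
    SITTING: PostureSpec(SITTING, {"waist": 10.0, "thigh": 85.0, "ankle": 20.0}),
    LYING: PostureSpec(LYING, {"waist": 85.0, "thigh": 88.0, "ankle": 88.0}),
    LEGS_OUTSTRETCHED: PostureSpec(
        LEGS_OUTSTRETCHED, {"waist": 40.0, "thigh": 85.0, "ankle": 80.0}
    ),
}

DEFAULT_DYNAMICS: dict[str, DynamicSpec] = {
    WALKING: DynamicSpec(WALKING, osc_amplitude=0.3, osc_freq=2.0, angle_sweep=40.0),
    STAIRS: DynamicSpec(STAIRS, osc_amplitude=0.3, osc_freq=1.5, angle_sweep=60.0),
}

#: Per-axis white measurement noise, g.
DEFAULT_NOISE_SD = 0.002

#: Ground-truthed protocol: two dynamic activities after the four postures.
DEFAULT_SEGMENT_ORDER = STATIC_LABELS + DYNAMIC_LABELS


def default_protocol(
    participant: str = "P1", segment_s: float = 90.0
) -> DayProtocol:
    """The ground-truthed activity block: 90 s of each of the six activities."""
    return DayProtocol(
        tuple((label, segment_s) for label in DEFAULT_SEGMENT_ORDER),
        participant=participant,
    )


def _gravity_at(theta_deg: np.ndarray) -> np.ndarray:
    """Gravity in the (pre-mount) sensor frame at inclination theta (degrees)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = np.zeros(th.shape + (3,))
    out[..., 1] = np.sin(th)
    out[..., 2] = np.cos(th)
    return out


def simulate_day(
    protocol: DayProtocol,
    postures: Mapping[str, PostureSpec] | None = None,
    dynamics: Mapping[str, DynamicSpec] | None = None,
    mount: MountModel | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | int | None = None,
    dynamic_base: str = STANDING,
) -> tuple[SensorRecording, AnnotationTrack]:
    """Simulate one participant-day and its exact ground-truth annotations.

    Static segments project gravity through each sensor's realised
    inclination angle; dynamic segments add a sinusoid of the configured
    amplitude/frequency along the sensor z-axis and sweep the inclination
    around the ``dynamic_base`` posture.  The mount rotation is applied to
    every sample, then white noise is added.

    Returns the recording and an annotation track that tiles the protocol.
    """
    postures = DEFAULT_POSTURES if postures is None else postures
    dynamics = DEFAULT_DYNAMICS if dynamics is None else dynamics
    if noise_sd < 0:
        raise ProtocolError("noise_sd must be >= 0")
    for label, _ in protocol.segments:
        if label not in postures and label not in dynamics:
            raise ProtocolError(f"protocol label {label!r} has no posture/dynamic spec")
    if not any(lab in postures and lab == STANDING for lab, _ in protocol.segments):
        raise ProtocolError("protocol must include a standing segment for calibration")
    if dynamic_base not in postures:
        raise ProtocolError(f"dynamic_base posture {dynamic_base!r} missing from posture set")

    rng = np.random.default_rng(rng)
    sensors = tuple(postures[STANDING].angles)
    mount = MountModel.identity(sensors) if mount is None else mount
    for sensor in sensors:
        if sensor not in mount.rotations:
            raise ProtocolError(f"mount model lacks a rotation for sensor {sensor!r}")

    fs = protocol.sample_rate
    n_total = int(round(protocol.duration_s() * fs))
    time = np.arange(n_total) / fs
    base_angles = postures[dynamic_base].angles

    signals = {s: np.empty((n_total, 3)) for s in sensors}
    intervals: list[Interval] = []
    t0 = 0.0
    i0 = 0
    for label, dur in protocol.segments:
        i1 = min(i0 + int(round(dur * fs)), n_total)
        t_seg = time[i0:i1]
        for sensor in sensors:
            wobble = rng.normal(0.0, mount.wobble_sd) if mount.wobble_sd > 0 else 0.0
            if label in postures:
                spec = postures[label]
                theta = spec.angles[sensor]
                if spec.jitter_sd > 0:
                    theta += rng.normal(0.0, spec.jitter_sd)
                theta = np.clip(theta + wobble, 0.0, 180.0)
                pre = _gravity_at(np.full(t_seg.size, theta))
            else:
                spec = dynamics[label]
                phase_sweep = rng.uniform(0.0, 2 * np.pi)
                phase_osc = rng.uniform(0.0, 2 * np.pi)
                # The sweep may cross 0 deg (limb swinging past vertical);
                # gravity projection handles signed angles naturally.
                theta = base_angles[sensor] + wobble + 0.5 * spec.angle_sweep * np.sin(
                    2 * np.pi * spec.osc_freq * t_seg + phase_sweep
                )
                pre = _gravity_at(theta)
                pre[:, 2] += spec.osc_amplitude * np.sin(
                    2 * np.pi * spec.osc_freq * t_seg + phase_osc
                )
            mounted = pre @ np.asarray(mount.rotations[sensor]).T
            signals[sensor][i0:i1] = mounted
        intervals.append(Interval(t0, t0 + dur, label))
        t0 += dur
        i0 = i1

    if noise_sd > 0:
        for sensor in sensors:
            signals[sensor] += rng.normal(0.0, noise_sd, size=(n_total, 3))

    recording = SensorRecording(sample_rate=fs, time=time, data=signals)
    return recording, AnnotationTrack(intervals)


@dataclass
class BenchmarkDay:
    """One simulated participant-day of the labelled benchmark."""

    recording: SensorRecording
    annotations: AnnotationTrack
    participant: str
    day: int

    def __iter__(self):
        # allow  rec, track = day  unpacking
        return iter((self.recording, self.annotations))


def make_benchmark(
    n_days: int = 15,
    seed: int = 0,
    n_participants: int = 5,
    segment_s: float = 90.0,
    postures: Mapping[str, PostureSpec] | None = None,
    dynamics: Mapping[str, DynamicSpec] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[BenchmarkDay]:
    """Simulate the labelled benchmark: ``n_days`` independent participant-days.

    Each day draws a fresh random mount orientation per sensor and runs the
    six-activity ground-truthed protocol (four static postures, walking,
    stairs; ``segment_s`` seconds each).  Days cycle through
    ``n_participants`` simulated participants so leave-one-subject-out
    evaluation has groups.  Deterministic given ``seed``.
    """
    if n_days < 1:
        raise ProtocolError("n_days must be >= 1")
    postures = DEFAULT_POSTURES if postures is None else postures
    sensors = tuple(postures[STANDING].angles)
    seeds = np.random.SeedSequence(seed).spawn(n_days)
    days = []
    for d in range(n_days):
        rng = np.random.default_rng(seeds[d])
        participant = f"P{d % n_participants + 1}"
        mount = MountModel.random(rng, sensors=sensors)
        rec, track = simulate_day(
            default_protocol(participant, segment_s=segment_s),
            postures=postures,
            dynamics=dynamics,
            mount=mount,
            noise_sd=noise_sd,
            rng=rng,
        )
        days.append(BenchmarkDay(rec, track, participant, d))
    return days


def sit_to_stand_protocol(
    n_cycles: int = 4,
    hold_s: float = 1.2,
    transition_s: float = 1.5,
    lead_in_s: float = 60.0,
    participant: str = "P1",
) -> DayProtocol:
    """Stress protocol of repeated sit-to-stand cycles.

    A standing lead-in provides the calibration segment, then each cycle is
    transition -> sitting hold -> transition -> standing hold.  Holds are
    short enough that any 3 s window overlaps a transition, while 0.5 s
    windows fit inside a hold — the window-size contrast the static/dynamic
    classifier exhibits on transitions.
    """
    segs: list[tuple[str, float]] = [(STANDING, lead_in_s)]
    for _ in range(n_cycles):
        segs.append(("sit_stand_transition", transition_s))
        segs.append((SITTING, hold_s))
        segs.append(("sit_stand_transition", transition_s))
        segs.append((STANDING, hold_s))
    return DayProtocol(tuple(segs), participant=participant)


#: Transition burst used by the sit-to-stand stress protocol.
SIT_STAND_TRANSITION = DynamicSpec(
    "sit_stand_transition", osc_amplitude=0.5, osc_freq=2.0, angle_sweep=70.0
)


def simulate_sit_to_stand(
    seed: int = 0, n_cycles: int = 4
) -> tuple[SensorRecording, AnnotationTrack]:
    """Simulate the sit-to-stand stress recording with default specs."""
    rng = np.random.default_rng(seed)
    protocol = sit_to_stand_protocol(n_cycles=n_cycles)
    dynamics = dict(DEFAULT_DYNAMICS)
    dynamics[SIT_STAND_TRANSITION.label] = SIT_STAND_TRANSITION
    mount = MountModel.random(rng)
    return simulate_day(protocol, dynamics=dynamics, mount=mount, rng=rng)
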
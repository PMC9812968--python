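"""Segment extraction, daily activity summaries and posture archetypes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PostureKitError
from .records import AnnotationTrack, Interval


@dataclass(frozen=True)
class ExtractedSegment:
    """A segment kept for analysis; ``truncated`` marks full-length extracts."""

    interval: Interval
    truncated: bool  # True if cut down to target_s, False if kept whole (short)


@dataclass
class DailySummary:
    """Time fractions over the five activity categories for one track."""

    participant: str
    day_tag: str
    fractions: dict[str, float]  # label -> percent of wear time
    total_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.fractions),
                "percent": list(self.fractions.values()),
            }
        )

    def bar_chart(self, width: int = 40) -> str:
        """Plain-text bar chart of the category fractions."""
        lines = []
        for label, pct in sorted(self.fractions.items(), key=lambda kv: -kv[1]):
            bar = "#" * int(round(pct / 100 * width))
            lines.append(f"{label:>18s} {pct:6.2f}% {bar}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PostureArchetype:
    """Median waist/thigh/ankle inclination of one posture (stick-figure data)."""

    label: str
    angles: dict[str, float]  # sensor -> median degrees


def extract_segments(
    track: AnnotationTrack, target_s: float = 90.0
) -> list[ExtractedSegment]:
    """Centred ``target_s`` sub-interval of every labelled interval.

    Centring keeps the extract away from both transitions of a long bout.
    Intervals shorter than ``target_s`` are kept whole and flagged.
    """
    if target_s <= 0:
        raise PostureKitError("target_s must be > 0")
    out = []
    for iv in track:
        if iv.duration_s > target_s:
            mid = 0.5 * (iv.start_s + iv.end_s)
            out.append(
                ExtractedSegment(
                    Interval(mid - target_s / 2, mid + target_s / 2, iv.label),
                    truncated=True,
                )
            )
        else:
            out.append(ExtractedSegment(iv, truncated=False))
    return out


def summarise_day(
    track: AnnotationTrack, participant: str = "", day_tag: str = ""
) -> DailySummary:
    """Per-category percentage of wear time for one day's track."""
    if len(track) == 0:
        raise PostureKitError("cannot summarise an empty track")
    track.check_no_overlap()
    totals: dict[str, float] = {}
    for iv in track:
        totals[iv.label] = totals.get(iv.label, 0.0) + iv.duration_s
    total_s = sum(totals.values())
    fractions = {label: 100.0 * dur / total_s for label, dur in totals.items()}
    return DailySummary(
        participant=participant, day_tag=day_tag, fractions=fractions, total_s=total_s
    )


def posture_archetypes(
    angle_series: dict[str, np.ndarray],
    time: np.ndarray,
    track: AnnotationTrack,
    labels: tuple[str, ...] | None = None,
) -> list[PostureArchetype]:
    """Median inclination angle per sensor for every posture in the track.

    ``angle_series`` maps sensor id to a dense angle series on ``time``.
    Postures with no samples are omitted (with a note to stderr via logging
    left to the caller).
    """
    sample_labels = track.sample_labels(np.asarray(time))
    wanted = labels if labels is not None else track.labels()
    out = []
    for label in wanted:
        mask = sample_labels == label
        if not mask.any():
            continue
        medians = {
            sensor: float(np.median(series[mask]))
            for sensor, series in angle_series.items()
        }
        out.append(PostureArchetype(label=label, angles=medians))
    return out


def archetype_table(archetypes: list[PostureArchetype]) -> pd.DataFrame:
    """Postures x sensors table of median angles (degrees)."""
    rows = {a.label: a.angles for a in archetypes}
    df = pd.DataFrame(rows).T
    df.index.name = "posture"
    return df


def compare_tracks(
    track_a: AnnotationTrack,
    track_b: AnnotationTrack,
    time: np.ndarray,
) -> pd.DataFrame:
    """Agreement matrix between two tracks (e.g. classifier vs diary).

    Rows are ``track_a`` labels, columns ``track_b`` labels; entries are the
    percentage of compared samples falling in each label pair.  Samples
    uncovered by either track are excluded.
    """
    time = np.asarray(time)
    a = track_a.sample_labels(time)
    b = track_b.sample_labels(time)
    mask = (a != "") & (b != "")
    if not mask.any():
        raise PostureKitError("tracks do not overlap in time")
    df = pd.crosstab(
        pd.Series(a[mask], name="track_a"), pd.Series(b[mask], name="track_b")
    )
    return 100.0 * df / mask.sum()
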
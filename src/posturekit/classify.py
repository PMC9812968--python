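"""Two-stage weighted-KNN cascade and its evaluation.

Classifier 1 separates static postures from dynamic movements using the 3 s
moving standard deviation of the thigh acceleration magnitude (optionally
also the thigh z-axis and waist magnitude).  Classifier 2 assigns one of
four postures (standing, sitting, lying, sitting with legs outstretched)
from the waist/thigh/ankle inclination angles on 1 s moving-mean
acceleration.  Both are weighted k-nearest-neighbour classifiers with a
Euclidean metric, 10 neighbours and inverse-squared-distance vote weights.

Voting conventions (fixed for reproducibility):

* a zero-distance neighbour dominates — if any neighbour coincides with the
  query, the vote is a plain majority among the zero-distance neighbours;
* ties in total weight break towards the lexicographically smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import ModelError
from .features import magnitude, moving_std
from .inclination import GravityMagnitude, inclination_arccos, moving_mean
from .records import AnnotationTrack, SensorRecording

DYNAMIC = "dynamic"
STATIC = "static"

#: Candidate Classifier-1 feature names, in canonical column order.
C1_FEATURES = ("movstd_thigh_magnitude", "movstd_thigh_z", "movstd_waist_magnitude")

#: The three feature combinations compared for Classifier 1.
C1_FEATURE_COMBOS = (
    C1_FEATURES[:1],
    C1_FEATURES[:2],
    C1_FEATURES[:3],
)


@dataclass
class KnnModel:
    """Stored training set plus the weighted-vote prediction rule (lazy learner)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    k: int = 10
    classes: np.ndarray = field(init=False)
    _index: NearestNeighbors = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ModelError("training matrix and labels are inconsistent")
        if np.isnan(self.X).any():
            raise ModelError("training features contain missing values")
        if self.k > len(self.X):
            raise ModelError(f"k={self.k} exceeds {len(self.X)} training rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise ModelError("feature_names do not match the training matrix width")
        self.classes = np.unique(self.y.astype(str))
        self._index = NearestNeighbors(n_neighbors=self.k).fit(self.X)


def knn_fit(
    X: np.ndarray,
    y,
    k: int = 10,
    feature_names: tuple[str, ...] | None = None,
) -> KnnModel:
    """Store the training data verbatim and build the neighbour index."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    return KnnModel(X=X, y=np.asarray(y, dtype=object), feature_names=tuple(feature_names), k=k)


def knn_predict(model: KnnModel, X: np.ndarray) -> np.ndarray:
    """Predict labels by inverse-squared-distance weighted vote of k neighbours."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.X.shape[1]:
        raise ModelError(
            f"query has {X.shape[1]} features, model expects {model.X.shape[1]}"
        )
    dist, idx = model._index.kneighbors(X)
    class_of = np.searchsorted(model.classes, model.y[idx].astype(str))
    n_query = X.shape[0]
    scores = np.zeros((n_query, model.classes.size))

    zero = dist <= 0.0
    has_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        weights = 1.0 / np.square(dist)
    # zero-distance dominance: plain majority among coincident neighbours
    weights[has_zero] = zero[has_zero].astype(float)

    rows = np.repeat(np.arange(n_query), model.k)
    np.add.at(scores, (rows, class_of.ravel()), weights.ravel())
    # argmax takes the first maximum; classes are sorted, so ties break
    # towards the lexicographically smallest label
    return model.classes[np.argmax(scores, axis=1)]


def classifier1_features(
    recording: SensorRecording,
    window_s: float = 3.0,
    feature_set: tuple[str, ...] = C1_FEATURES[:1],
    thigh: str = "thigh",
    waist: str = "waist",
) -> np.ndarray:
    """Dense static/dynamic feature matrix (one row per sample).

    ``recording`` must already be gravity-aligned and low-pass filtered.
    """
    fs = recording.sample_rate
    columns = []
    for name in feature_set:
        if name == "movstd_thigh_magnitude":
            series = magnitude(recording, thigh)
        elif name == "movstd_thigh_z":
            series = recording.get(thigh)[:, 2]
        elif name == "movstd_waist_magnitude":
            series = magnitude(recording, waist)
        else:
            raise ModelError(f"unknown classifier-1 feature {name!r}")
        columns.append(moving_std(series, window_s, fs))
    return np.column_stack(columns)


def classifier2_features(
    recording: SensorRecording,
    g: dict[str, GravityMagnitude] | float,
    window_s: float = 1.0,
    sensors: tuple[str, ...] = ("waist", "thigh", "ankle"),
) -> np.ndarray:
    """Dense posture feature matrix: inclination angle per sensor (degrees).

    ``recording`` must be gravity-aligned (and normally low-pass filtered);
    each sensor's z-component is smoothed with a centred ``window_s`` moving
    mean before the arccos.
    """
    recording.require(sensors)
    cols = []
    for sensor in sensors:
        sz = moving_mean(recording.get(sensor)[:, 2], window_s, recording.sample_rate)
        gs = g[sensor] if isinstance(g, dict) else g
        cols.append(inclination_arccos(sz, gs))
    return np.column_stack(cols)


def cascade_predict(
    recording: SensorRecording,
    model1: KnnModel,
    model2: KnnModel,
    g: dict[str, GravityMagnitude] | float = 1.0,
    window1_s: float = 3.0,
    feature_set: tuple[str, ...] = C1_FEATURES[:1],
    sensors: tuple[str, ...] = ("waist", "thigh", "ankle"),
) -> tuple[AnnotationTrack, np.ndarray]:
    """Per-sample five-category labels from the two-classifier cascade.

    Every sample Classifier 1 deems dynamic is labelled ``dynamic``; all
    others receive Classifier 2's posture.  Returns the merged interval
    track and the dense per-sample labels (contiguous equal labels are
    merged purely for presentation).
    """
    if model1 is None or model2 is None:
        raise ModelError("both cascade models must be trained")
    X1 = classifier1_features(recording, window_s=window1_s, feature_set=feature_set)
    X2 = classifier2_features(recording, g=g, sensors=sensors)
    stat_dyn = knn_predict(model1, X1)
    postures = knn_predict(model2, X2)
    labels = np.where(stat_dyn == DYNAMIC, DYNAMIC, postures).astype(object)
    track = AnnotationTrack.from_samples(recording.time, labels, recording.sample_rate)
    return track, labels


def combine_legs(
    track_right: AnnotationTrack,
    track_left: AnnotationTrack,
    time: np.ndarray,
    sample_rate: float,
    right_postures: np.ndarray | None = None,
) -> AnnotationTrack:
    """Bilateral rule: a sample is dynamic only if *both* legs are dynamic.

    One moving leg does not end a static posture.  Where the right leg alone
    is dynamic, the emitted posture comes from the right-leg posture
    classifier (``right_postures``, dense per-sample labels); if those are
    not supplied the left leg's static label is used.
    """
    right = track_right.sample_labels(time)
    left = track_left.sample_labels(time)
    if (right == "").any() or (left == "").any():
        raise ModelError("leg tracks do not share the sample time base")
    both_dynamic = (right == DYNAMIC) & (left == DYNAMIC)
    out = right.copy()
    right_only = (right == DYNAMIC) & ~both_dynamic
    if right_postures is not None:
        out[right_only] = right_postures[right_only]
    else:
        out[right_only] = left[right_only]
    out[both_dynamic] = DYNAMIC
    return AnnotationTrack.from_samples(time, out, sample_rate)


@dataclass
class EvaluationReport:
    """Cross-validated accuracy with an aggregated confusion matrix."""

    scheme: str
    accuracy: float  # percent
    confusion: pd.DataFrame  # true class x predicted class counts
    fold_accuracies: list[float]
    classes: tuple[str, ...]
    notes: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(self.confusion.to_numpy().sum())


def evaluate(
    X: np.ndarray,
    y,
    scheme: str = "kfold5",
    groups=None,
    seed: int = 0,
    k: int = 10,
) -> EvaluationReport:
    """Cross-validate a weighted KNN on (X, y).

    ``scheme`` is ``kfold5`` (stratified, shuffled with ``seed``) or ``loso``
    (leave-one-group-out; ``groups`` are participant ids).  The confusion
    matrix aggregates test predictions over all folds; accuracy is
    trace/total in percent.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=object)
    classes = tuple(np.unique(y.astype(str)))
    if scheme == "kfold5":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        split = splitter.split(X, y.astype(str))
    elif scheme == "loso":
        if groups is None:
            raise ModelError("leave-one-subject-out needs participant groups")
        splitter = LeaveOneGroupOut()
        split = splitter.split(X, y.astype(str), groups=np.asarray(groups))
    else:
        raise ModelError(f"unknown evaluation scheme {scheme!r}")

    total = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accuracies = []
    notes = []
    for fold, (tr, te) in enumerate(split):
        missing = set(classes) - set(np.unique(y[tr].astype(str)))
        if missing:
            notes.append(f"fold {fold}: classes absent from training: {sorted(missing)}")
        model = knn_fit(X[tr], y[tr], k=min(k, len(tr)))
        pred = knn_predict(model, X[te])
        cm = (
            pd.crosstab(pd.Series(y[te].astype(str)), pd.Series(pred.astype(str)))
            .reindex(index=list(classes), columns=list(classes), fill_value=0)
            .to_numpy()
        )
        total += cm
        fold_accuracies.append(100.0 * np.trace(cm) / cm.sum())

    confusion = pd.DataFrame(total, index=list(classes), columns=list(classes))
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    accuracy = 100.0 * np.trace(total) / total.sum()
    return EvaluationReport(
        scheme=scheme,
        accuracy=float(accuracy),
        confusion=confusion,
        fold_accuracies=fold_accuracies,
        classes=classes,
        notes=notes,
    )
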
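import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturekit as pk
from posturekit.classify import DYNAMIC, combine_legs, evaluate, knn_fit, knn_predict
from posturekit.errors import ModelError
from posturekit.records import AnnotationTrack, Interval
from posturekit.synthetic import DYNAMIC_LABELS, MountModel, PostureSpec, DayProtocol, simulate_day


def brute_force_knn(Xtr, ytr, Xq, k):
    """Exhaustive all-pairs oracle with the same voting conventions."""
    Xtr = np.asarray(Xtr, float)
    Xq = np.asarray(Xq, float)
    if Xtr.ndim == 1:
        Xtr = Xtr[:, None]
    if Xq.ndim == 1:
        Xq = Xq[:, None]
    ytr = np.asarray(ytr, dtype=object)
    classes = sorted(np.unique(ytr.astype(str)))
    preds = []
    for q in Xq:
        d = np.sqrt(((Xtr - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        dk, lk = d[order], ytr[order].astype(str)
        if (dk == 0).any():
            zl = lk[dk == 0]
            counts = {c: int((zl == c).sum()) for c in classes}
        else:
            counts = {c: float((1.0 / dk[lk == c] ** 2).sum()) for c in classes}
        preds.append(sorted(classes, key=lambda c: (-counts[c], c))[0])
    return np.array(preds, dtype=object)


class TestKnn:
    def test_single_training_row_predicts_its_label_everywhere(self):
        model = knn_fit(np.array([[1.0, 2.0]]), ["up"], k=1)
        pred = knn_predict(model, np.array([[0.0, 0.0], [100.0, -3.0]]))
        assert list(pred) == ["up", "up"]

    def test_hand_computed_inverse_square_weights(self):
        # neighbours of 0.5: A at d=0.5 (w=4), A at d=0.5 (w=4), B at d=9.5
        model = knn_fit(np.array([0.0, 1.0, 10.0]), ["A", "A", "B"], k=3)
        assert knn_predict(model, np.array([0.5]))[0] == "A"

    def test_query_on_training_row_is_dominated_by_zero_distance(self):
        X = np.array([0.0, 0.0, 0.1, 0.2, 0.3])
        y = ["B", "B", "A", "A", "A"]
        model = knn_fit(X, y, k=5)
        assert knn_predict(model, np.array([0.0]))[0] == "B"

    def test_zero_distance_conflict_breaks_ties_lexicographically(self):
        model = knn_fit(np.array([1.0, 1.0]), ["beta", "alpha"], k=2)
        assert knn_predict(model, np.array([1.0]))[0] == "alpha"

    def test_symmetric_tie_breaks_by_label_sort_order(self):
        model = knn_fit(np.array([-1.0, 1.0]), ["zeta", "eta"], k=2)
        assert knn_predict(model, np.array([0.0]))[0] == "eta"

    def test_k_larger_than_training_set_fails(self):
        with pytest.raises(ModelError):
            knn_fit(np.array([[0.0], [1.0]]), ["a", "b"], k=10)

    def test_dimension_mismatch_fails(self):
        model = knn_fit(np.array([[0.0, 1.0]]), ["a"], k=1)
        with pytest.raises(ModelError):
            knn_predict(model, np.array([[0.0, 1.0, 2.0]]))

    def test_two_separated_clusters_have_a_midpoint_boundary(self):
        X = np.concatenate([np.zeros(10), np.ones(10) * 10.0])
        y = ["low"] * 10 + ["high"] * 10
        model = knn_fit(X, y, k=10)
        queries = np.array([1.0, 4.0, 6.0, 9.0])
        assert list(knn_predict(model, queries)) == list(brute_force_knn(X, y, queries[:, None], 10))
        assert list(knn_predict(model, np.array([1.0, 9.0]))) == ["low", "high"]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(11, 200),
        dim=st.integers(1, 4),
        k=st.integers(1, 10),
        n_classes=st.integers(2, 4),
    )
    def test_matches_brute_force_oracle_on_random_instances(self, seed, n, dim, k, n_classes):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, dim))
        y = rng.choice([f"c{i}" for i in range(n_classes)], size=n)
        Xq = rng.uniform(-1.2, 1.2, size=(25, dim))
        model = knn_fit(X, y, k=k)
        assert list(knn_predict(model, Xq)) == list(brute_force_knn(X, y, Xq, k))


class TestCombineLegs:
    def _track(self, labels, fs=50.0):
        time = np.arange(len(labels)) / fs
        return AnnotationTrack.from_samples(time, np.array(labels, dtype=object), fs), time

    def test_one_moving_leg_stays_static(self):
        right, time = self._track([DYNAMIC] * 50)
        left, _ = self._track(["sitting"] * 50)
        out = combine_legs(right, left, time, 50.0, right_postures=np.array(["standing"] * 50, dtype=object))
        assert [iv.label for iv in out] == ["standing"]

    def test_both_legs_moving_is_dynamic(self):
        right, time = self._track([DYNAMIC] * 50)
        left, _ = self._track([DYNAMIC] * 50)
        out = combine_legs(right, left, time, 50.0)
        assert [iv.label for iv in out] == [DYNAMIC]

    def test_both_static_keeps_right_leg_posture(self):
        right, time = self._track(["sitting"] * 50)
        left, _ = self._track(["lying"] * 50)
        out = combine_legs(right, left, time, 50.0)
        assert [iv.label for iv in out] == ["sitting"]

    def test_mismatched_time_bases_fail(self):
        right, time = self._track([DYNAMIC] * 50)
        left, _ = self._track([DYNAMIC] * 30)
        with pytest.raises(ModelError):
            combine_legs(right, left, np.concatenate([time, time]), 50.0)


class TestEvaluate:
    def test_single_class_gives_perfect_one_by_one_confusion(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        rep = evaluate(X, ["only"] * 50, scheme="kfold5", seed=0, k=3)
        assert rep.accuracy == 100.0
        assert rep.confusion.shape == (1, 1)

    def test_loso_requires_groups(self):
        with pytest.raises(ModelError):
            evaluate(np.zeros((20, 1)), ["a"] * 10 + ["b"] * 10, scheme="loso")

    def test_confusion_row_sums_equal_class_counts(self, small_benchmark):
        prepared = pk.prepare_benchmark(small_benchmark)
        X, y, groups = pk.posture_dataset(prepared)
        rep = evaluate(X, y, scheme="loso", groups=groups)
        counts = {c: int((y == c).sum()) for c in rep.classes}
        assert rep.confusion.sum(axis=1).to_dict() == counts
        assert rep.accuracy == pytest.approx(
            100.0 * np.trace(rep.confusion.to_numpy()) / rep.n_samples
        )

    def test_permuted_labels_fall_to_chance_level(self, small_benchmark):
        prepared = pk.prepare_benchmark(small_benchmark)
        X, y, _ = pk.posture_dataset(prepared)
        rng = np.random.default_rng(0)
        rep = evaluate(X, rng.permutation(y), scheme="kfold5", seed=0)
        assert rep.accuracy == pytest.approx(25.0, abs=4.0)


class TestCascade:
    def test_pure_standing_day_yields_a_single_standing_interval(self, small_benchmark):
        prepared = pk.prepare_benchmark(small_benchmark)
        X1, y1, _ = pk.static_dynamic_dataset(prepared)
        X2, y2, _ = pk.posture_dataset(prepared)
        m1 = pk.knn_fit(X1, y1)
        m2 = pk.knn_fit(X2, y2)
        rec, track = simulate_day(
            DayProtocol((("standing", 30.0),)),
            mount=MountModel.random(np.random.default_rng(3), sensors=("waist", "thigh", "ankle")),
            rng=3,
        )
        prep = pk.prepare_day(rec, track)
        out, labels = pk.cascade_predict(pk.lowpass(prep.aligned), m1, m2, g=prep.gravity)
        assert [iv.label for iv in out] == ["standing"]
        assert set(labels) == {"standing"}

    def test_benchmark_day_recovered_away_from_boundaries(self, small_benchmark):
        prepared = pk.prepare_benchmark(small_benchmark)
        X1, y1, _ = pk.static_dynamic_dataset(prepared)
        X2, y2, _ = pk.posture_dataset(prepared)
        m1 = pk.knn_fit(X1, y1)
        m2 = pk.knn_fit(X2, y2)
        day = prepared[0]
        _, labels = pk.cascade_predict(pk.lowpass(day.aligned), m1, m2, g=day.gravity)
        time = day.aligned.time
        truth = day.annotations.sample_labels(time)
        truth = np.where(np.isin(truth, list(DYNAMIC_LABELS)), DYNAMIC, truth)
        away = np.ones(time.size, dtype=bool)
        for iv in day.annotations:
            away &= np.abs(time - iv.start_s) > 2.0
        away &= time < day.annotations.end_s - 2.0
        agreement = np.mean(labels[away] == truth[away])
        assert agreement >= 0.99
        # every sample gets exactly one of the five categories
        assert set(labels) <= set(list(day.annotations.labels())[:4] + [DYNAMIC])
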
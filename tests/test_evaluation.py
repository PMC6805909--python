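"""Stratified splitting, k-NN, random forest, F1 metrics and repetition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from shellfeat.evaluation import (
    FeatureTable,
    accuracy,
    confusion_matrix,
    knn_predict,
    macro_f1,
    make_classifier,
    mean_ci,
    micro_f1,
    parameter_sweep,
    repeat_eval,
    rf_predict,
    stratified_split,
)


def toy_table(labels, values, kind="toy"):
    labels = np.asarray(labels, dtype=str)
    ids = np.array([f"s{i}" for i in range(len(labels))])
    return FeatureTable(labels, ids, np.asarray(values, dtype=float), kind)


def gaussian_clusters(n_classes=5, per_class=10, d=10, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centres = rng.normal(scale=sep, size=(n_classes, d))
    labels, rows = [], []
    for i, c in enumerate(centres):
        rows.append(c + rng.normal(size=(per_class, d)))
        labels += [f"c{i}"] * per_class
    return toy_table(labels, np.vstack(rows))


class TestStratifiedSplit:
    def test_134_classes_of_10_split_938_to_402(self):
        labels = np.repeat([f"sp{i:03d}" for i in range(134)], 10)
        table = toy_table(labels, np.zeros((1340, 2)))
        train, test = stratified_split(table, seed=0)
        assert len(train) == 938 and len(test) == 402  # 134*7 / 134*3
        for lab in np.unique(labels):
            assert (train.species == lab).sum() == 7
            assert (test.species == lab).sum() == 3

    def test_split_partitions_all_samples(self):
        table = gaussian_clusters()
        train, test = stratified_split(table, seed=1)
        assert sorted(np.r_[train.sample_ids, test.sample_ids]) == sorted(table.sample_ids)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)

    def test_two_seeds_differ_with_identical_class_counts(self):
        table = gaussian_clusters()
        tr1, _ = stratified_split(table, seed=1)
        tr2, _ = stratified_split(table, seed=2)
        assert sorted(tr1.sample_ids) != sorted(tr2.sample_ids)
        for lab in np.unique(table.species):
            assert (tr1.species == lab).sum() == (tr2.species == lab).sum() == 7

    def test_same_seed_reproduces_split(self):
        table = gaussian_clusters()
        tr1, _ = stratified_split(table, seed=5)
        tr2, _ = stratified_split(table, seed=5)
        np.testing.assert_array_equal(tr1.sample_ids, tr2.sample_ids)

    def test_singleton_class_rejected_by_name(self):
        table = toy_table(["a", "a", "lonely"], np.zeros((3, 2)))
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(table)


class TestKNN:
    def test_k1_assigns_nearest_neighbour_label(self):
        train = toy_table(["a", "b"], [[0.0], [10.0]])
        test = toy_table(["?", "?"], [[1.0], [9.0]])
        np.testing.assert_array_equal(knn_predict(train, test, k=1), ["a", "b"])

    def test_three_vs_five_neighbour_vote_flip(self):
        # toy 2-D geometry: within the k=3 circle sit 2 triangles and
        # 1 square, within k=5 sit 2 triangles and 3 squares -> the vote
        # flips from triangle to square as k grows
        train = toy_table(
            ["triangle", "square", "triangle", "square", "square", "triangle"],
            [[1.0, 0], [0, 1.5], [-2.0, 0], [0, -2.5], [2.6, 0], [0, 3.5]],
        )
        test = toy_table(["?"], [[0.0, 0.0]])
        assert knn_predict(train, test, k=3)[0] == "triangle"
        assert knn_predict(train, test, k=5)[0] == "square"

    def test_vote_tie_broken_by_nearest_member(self):
        train = toy_table(["a", "b", "b", "a"], [[1.0], [-1.5], [2.0], [-3.0]])
        # k=4: two of each; nearest neighbour overall has label 'a'
        assert knn_predict(toy_table(["a", "b"], [[1.0], [-1.5]]),
                           toy_table(["?"], [[0.0]]), k=2)[0] == "a"
        assert knn_predict(train, toy_table(["?"], [[0.0]]), k=4)[0] == "a"

    def test_predictions_match_exhaustive_distance_scan(self):
        rng = np.random.default_rng(12)
        train = toy_table(rng.choice(list("abc"), 50), rng.normal(size=(50, 4)))
        test = toy_table(["?"] * 20, rng.normal(size=(20, 4)))
        for k in (1, 3, 7):
            preds = knn_predict(train, test, k=k)
            for i in range(20):
                d = np.sqrt(((train.values - test.values[i]) ** 2).sum(axis=1))
                order = np.argsort(d, kind="stable")[:k]
                votes = {}
                for j in order:
                    votes[train.species[j]] = votes.get(train.species[j], 0) + 1
                best = max(votes.values())
                tied = {lab for lab, v in votes.items() if v == best}
                expected = next(train.species[j] for j in order if train.species[j] in tied)
                assert preds[i] == expected

    def test_k_bounds_enforced(self):
        train = toy_table(["a", "b"], [[0.0], [1.0]])
        test = toy_table(["?"], [[0.5]])
        with pytest.raises(ValueError):
            knn_predict(train, test, k=0)
        with pytest.raises(ValueError):
            knn_predict(train, test, k=3)

    def test_k1_on_own_training_set_is_perfect(self):
        table = gaussian_clusters(seed=3)
        preds = knn_predict(table, table, k=1)
        np.testing.assert_array_equal(preds, table.species)


class TestRandomForest:
    def test_single_class_always_predicted(self):
        train = toy_table(["only"] * 5, np.random.default_rng(0).normal(size=(5, 3)))
        test = toy_table(["?"] * 4, np.random.default_rng(1).normal(size=(4, 3)))
        assert set(rf_predict(train, test, n_trees=10, seed=0)) == {"only"}

    def test_separable_clusters_classified_perfectly(self):
        table = gaussian_clusters(n_classes=2, per_class=50, d=10, sep=5.0, seed=4)
        train, test = stratified_split(table, seed=0)
        preds = rf_predict(train, test, n_trees=100, seed=0)
        assert (preds == test.species).all()

    def test_same_seed_identical_predictions(self):
        table = gaussian_clusters(sep=1.0, seed=5)
        train, test = stratified_split(table, seed=0)
        p1 = rf_predict(train, test, n_trees=20, seed=7)
        p2 = rf_predict(train, test, n_trees=20, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_tree_count_validated(self):
        table = gaussian_clusters()
        with pytest.raises(ValueError):
            rf_predict(table, table, n_trees=0)


class TestMetrics:
    def test_perfect_diagonal_matrix(self):
        cm = confusion_matrix(list("aabbcc"), list("aabbcc"))
        assert micro_f1(cm) == 1.0 and accuracy(cm) == 1.0 and macro_f1(cm) == 1.0

    def test_three_class_matrix_with_four_of_six_correct(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "a", "b", "c", "c", "a"]
        cm = confusion_matrix(y_true, y_pred)
        assert np.trace(cm.counts) == 4
        assert micro_f1(cm) == pytest.approx(2 * 4 / (2 * 4 + 2 + 2))
        assert accuracy(cm) == pytest.approx(2 / 3)

    def test_micro_f1_equals_accuracy_for_single_label_multiclass(self):
        rng = np.random.default_rng(100)
        from shellfeat.evaluation import ConfusionMatrix

        for _ in range(500):
            n = rng.integers(2, 8)
            counts = rng.integers(0, 20, size=(n, n))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts, tuple(map(str, range(n))))
            assert micro_f1(cm) == pytest.approx(accuracy(cm), abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        counts=st.integers(2, 6).flatmap(
            lambda n: arrays(np.int64, (n, n), elements=st.integers(0, 30))
        )
    )
    def test_micro_f1_accuracy_identity_holds_for_any_matrix(self, counts):
        from shellfeat.evaluation import ConfusionMatrix

        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix(counts, tuple(map(str, range(len(counts)))))
        assert micro_f1(cm) == pytest.approx(accuracy(cm), abs=1e-12)
        assert 0.0 <= macro_f1(cm) <= 1.0

    def test_empty_matrix_rejected(self):
        from shellfeat.evaluation import ConfusionMatrix

        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ("a", "b"))
        for metric in (accuracy, micro_f1, macro_f1):
            with pytest.raises(ValueError):
                metric(cm)

    def test_macro_f1_differs_from_accuracy_under_imbalance(self):
        y_true = ["a"] * 9 + ["b"]
        y_pred = ["a"] * 10
        cm = confusion_matrix(y_true, y_pred)
        assert accuracy(cm) == pytest.approx(0.9)
        assert macro_f1(cm) < accuracy(cm)


class TestRepeatEval:
    def test_t_interval_closed_form(self):
        mean, hw = mean_ci([0.7, 0.8])
        assert mean == pytest.approx(0.75)
        assert hw == pytest.approx(0.6353102368216048, abs=1e-9)

    def test_single_repetition_warns_and_reports_zero_halfwidth(self):
        table = gaussian_clusters()
        with pytest.warns(UserWarning, match="single repetition"):
            res = repeat_eval(table, make_classifier("knn", k=1), repetitions=1)
        assert res.ci("accuracy") == 0.0

    def test_constant_metric_gives_zero_halfwidth(self):
        table = gaussian_clusters(sep=50.0)  # trivially separable
        res = repeat_eval(table, make_classifier("knn", k=1), repetitions=5)
        assert res.mean("accuracy") == 1.0 and res.ci("accuracy") == 0.0

    def test_means_bounded_and_halfwidths_shrink_with_repetitions(self):
        table = gaussian_clusters(sep=1.0, seed=8)  # overlapping clusters
        r10 = repeat_eval(table, make_classifier("knn", k=3), repetitions=10, seed=1)
        r100 = repeat_eval(table, make_classifier("knn", k=3), repetitions=100, seed=1)
        for r in (r10, r100):
            for name in ("accuracy", "micro_f1", "macro_f1"):
                assert 0.0 <= r.mean(name) <= 1.0
        assert r100.ci("accuracy") < r10.ci("accuracy")

    def test_deterministic_for_fixed_seed(self):
        table = gaussian_clusters(sep=1.5, seed=2)
        r1 = repeat_eval(table, make_classifier("rf", n_trees=10), repetitions=3, seed=9)
        r2 = repeat_eval(table, make_classifier("rf", n_trees=10), repetitions=3, seed=9)
        assert r1.metrics == r2.metrics


class TestParameterSweep:
    def test_single_point_grid_equals_repeat_eval(self):
        table = gaussian_clusters(sep=1.0, seed=6)
        curve, best = parameter_sweep(table, "knn", [3], repetitions=5, seed=4)
        direct = repeat_eval(table, make_classifier("knn", k=3), repetitions=5, seed=4)
        assert len(curve) == 1 and best == 3
        assert curve[0].metrics == direct.metrics

    def test_accuracy_curve_bounded_over_k_grid(self):
        table = gaussian_clusters(sep=1.0, seed=7)
        curve, best = parameter_sweep(table, "knn", [1, 3, 5, 7], repetitions=5, seed=0)
        assert best in (1, 3, 5, 7)
        for r in curve:
            assert 0.0 <= r.mean("accuracy") <= 1.0

    def test_duplicate_twin_dataset_perfect_at_k1(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(20, 3))
        values = np.repeat(base, 2, axis=0)  # every sample has an identical twin
        labels = np.repeat([f"c{i}" for i in range(10)], 4)
        table = toy_table(labels, values)
        curve, _ = parameter_sweep(table, "knn", [1], repetitions=10, seed=3)
        assert curve[0].mean("accuracy") == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            parameter_sweep(gaussian_clusters(), "knn", [])
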
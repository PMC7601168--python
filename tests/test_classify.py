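import numpy as np
import pandas as pd
import pytest

from fluortex.classify import (
    ConfusionCounts,
    grouped_cv,
    knn_fit,
    knn_predict,
    metrics,
)


def _table(values, labels, image_id="img", group_id=0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(labels) > 1:
        values = values.T
    df = pd.DataFrame(values, columns=[f"f{i}" for i in range(values.shape[1])])
    df["label"] = labels
    df["image_id"] = image_id
    df["group_id"] = group_id
    df["window_row"] = range(len(df))
    df["window_col"] = 0
    return df


class TestKnn:
    def test_stores_all_training_vectors(self):
        table = _table(np.arange(10.0), [0, 1] * 5)
        model = knn_fit(table, ["f0"], k=1)
        assert model.X.shape == (10, 1)

    def test_training_point_predicts_its_own_label(self):
        table = _table([[0.0, 1.0], [5.0, 2.0], [9.0, -1.0], [4.0, 4.0]], [0, 1, 0, 1])
        model = knn_fit(table, ["f0", "f1"], k=1)
        for _, row in table.iterrows():
            assert knn_predict(model, row[["f0", "f1"]].to_numpy()) == row["label"]

    def test_nearest_neighbor_by_distance(self):
        table = _table([0.0, 10.0, 0.0, 10.0], [0, 1, 0, 1])
        model = knn_fit(table, ["f0"], k=1)
        assert knn_predict(model, np.array([2.0])) == 0
        assert knn_predict(model, np.array([8.0])) == 1

    def test_majority_vote_k3(self):
        table = _table([0.0, 1.0, 2.0, 50.0], [0, 0, 1, 1])
        model = knn_fit(table, ["f0"], k=3)
        # 3 nearest of query 1.0: labels {0, 0, 1} -> standard
        assert knn_predict(model, np.array([1.0])) == 0

    def test_even_k_tie_breaks_toward_anomalous(self):
        table = _table([0.0, 10.0], [0, 1])
        model = knn_fit(table, ["f0"], k=2)
        assert knn_predict(model, np.array([5.0])) == 1

    def test_zero_variance_feature_dropped_with_warning(self):
        table = _table([[0.0, 7.0], [1.0, 7.0], [2.0, 7.0], [3.0, 7.0]], [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = knn_fit(table, ["f0", "f1"], k=1)
        assert model.features == ["f0"]

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(columns=["f0", "label", "image_id", "group_id"])
        with pytest.raises(ValueError, match="empty"):
            knn_fit(empty, ["f0"], k=1)

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError, match="k"):
            knn_fit(_table([0.0, 1.0], [0, 1]), ["f0"], k=3)

    def test_dimension_mismatch_rejected(self):
        model = knn_fit(_table([0.0, 1.0], [0, 1]), ["f0"], k=1)
        with pytest.raises(ValueError, match="features"):
            knn_predict(model, np.array([1.0, 2.0]))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert m.as_tuple() == (1.0, 1.0, 1.0)

    def test_direct_substitution(self):
        m = metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.7)

    def test_all_standard_predictor(self):
        m = metrics(ConfusionCounts(TP=0, FN=5, TN=5, FP=0))
        assert m.as_tuple() == (0.0, 1.0, 0.5)

    def test_zero_denominators_flagged_undefined(self):
        m = metrics(ConfusionCounts(TP=0, FN=0, TN=4, FP=1))
        assert not m.defined("sensitivity")
        assert m.defined("specificity")
        m2 = metrics(ConfusionCounts())
        assert not any(m2.defined(n) for n in ("sensitivity", "specificity", "accuracy"))

    def test_counts_validate_nonnegative(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1)


class TestGroupedCV:
    def _dataset(self, n_images, n_groups, rng, n_windows=12):
        frames = []
        per_group = n_images // n_groups
        for i in range(n_images):
            labels = rng.integers(0, 2, n_windows)
            values = np.where(labels == 1, 10.0, 0.0) + rng.normal(0, 1, n_windows)
            frames.append(
                _table(values, labels, image_id=f"img{i}", group_id=i // per_group)
            )
        return pd.concat(frames, ignore_index=True)

    def test_single_group_of_five_gives_five_folds(self, rng):
        report = grouped_cv(self._dataset(5, 1, rng), ["f0"], k=1)
        assert len(report.folds) == 5
        assert sorted(report.folds["image_id"]) == [f"img{i}" for i in range(5)]

    def test_two_groups_of_five_give_ten_folds(self, rng):
        report = grouped_cv(self._dataset(10, 2, rng), ["f0"], k=1)
        assert len(report.folds) == 10

    def test_degenerate_group_of_two(self, rng):
        report = grouped_cv(self._dataset(2, 1, rng), ["f0"], k=1)
        assert len(report.folds) == 2

    def test_group_with_single_image_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            grouped_cv(self._dataset(3, 3, rng), ["f0"], k=1)

    def test_no_leakage_of_test_image_into_training(self):
        """Two images with flipped label conventions: with k=1, a leaked
        same-image neighbor (distance 0) would predict the truth
        perfectly; honest cross-image training must get everything
        wrong."""
        a = _table([0.0, 0.0, 10.0, 10.0], [0, 0, 1, 1], image_id="a")
        b = _table([0.0, 0.0, 10.0, 10.0], [1, 1, 0, 0], image_id="b")
        report = grouped_cv(pd.concat([a, b], ignore_index=True), ["f0"], k=1)
        assert report.folds["accuracy"].tolist() == [0.0, 0.0]

    def test_fold_confusion_counts_cover_all_superpixels(self, rng):
        table = self._dataset(4, 2, rng)
        report = grouped_cv(table, ["f0"], k=1)
        assert report.pooled_counts().total == len(table)

    def test_aggregate_mean_matches_fold_metrics(self, rng):
        report = grouped_cv(self._dataset(4, 2, rng), ["f0"], k=1)
        accs = report.folds["accuracy"].to_numpy()
        mean, sd = report.aggregate["accuracy"]
        assert mean == pytest.approx(np.nanmean(accs))
        assert sd == pytest.approx(np.nanstd(accs))

    def test_superpixel_order_does_not_change_fold_counts(self, rng):
        table = self._dataset(4, 2, rng)
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        r1 = grouped_cv(table, ["f0"], k=1)
        r2 = grouped_cv(shuffled, ["f0"], k=1)
        cols = ["image_id", "TP", "FP", "TN", "FN"]
        pd.testing.assert_frame_equal(
            r1.folds[cols].sort_values("image_id").reset_index(drop=True),
            r2.folds[cols].sort_values("image_id").reset_index(drop=True),
        )

    def test_summary_and_json_render(self, rng):
        report = grouped_cv(self._dataset(4, 2, rng), ["f0"], k=1)
        assert "folds" in report.to_json()
        assert "sensitivity" in report.summary()
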
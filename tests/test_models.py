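import numpy as np
import pytest
from sklearn.metrics import f1_score

from specklesense.exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)
from specklesense.models import (
    FeatureMatrix,
    GlucoseSVM,
    SVMResults,
    build_ml_features,
    evaluate_classifier,
    frame_difference_stack,
    predict,
    stratified_split,
    train_svm,
)


class TestFrameDifference:
    def test_constant_video_yields_zero_stack(self):
        stack = frame_difference_stack(np.ones((5, 4, 4)))
        np.testing.assert_array_equal(stack.frames, 0.0)

    def test_count_is_frames_minus_one(self):
        video = np.random.default_rng(0).random((2501, 4, 4))
        assert frame_difference_stack(video).frames.shape[0] == 2500

    def test_scalar_example_scaling(self):
        # frames (0, 1, 3): raw diffs (1, 2) scale to (0.5, 1) with floor 0
        video = np.array([0.0, 1.0, 3.0]).reshape(3, 1, 1)
        np.testing.assert_allclose(
            frame_difference_stack(video).frames.ravel(), [0.5, 1.0]
        )

    def test_output_in_unit_interval(self):
        video = np.random.default_rng(1).random((20, 8, 8))
        frames = frame_difference_stack(video).frames
        assert frames.min() >= 0.0 and frames.max() <= 1.0

    def test_single_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            frame_difference_stack(np.ones((1, 4, 4)))


class TestBuildMlFeatures:
    def test_length_preserving_concatenation(self):
        x = np.sin(np.linspace(0, 6, 250))
        y = np.cos(np.linspace(0, 6, 250))
        row = build_ml_features(x, y, target_length=500)
        assert row.shape == (500,)
        np.testing.assert_allclose(row[:250], x)
        np.testing.assert_allclose(row[250:], y)

    def test_linear_ramp_stays_linear_after_resampling(self):
        ramp = np.linspace(-2.0, 3.0, 1000)
        row = build_ml_features(ramp, ramp, target_length=100)
        half = row[:50]
        assert half[0] == pytest.approx(-2.0)
        assert half[-1] == pytest.approx(3.0)
        np.testing.assert_allclose(np.diff(half), np.diff(half)[0], rtol=1e-9)

    def test_zscore_option_standardizes_row(self):
        rng = np.random.default_rng(2)
        row = build_ml_features(
            rng.standard_normal(300), rng.standard_normal(300), scale="zscore"
        )
        assert row.mean() == pytest.approx(0.0, abs=1e-12)
        assert row.std() == pytest.approx(1.0, rel=1e-12)

    def test_constant_channel_rejected_under_zscore(self):
        with pytest.raises(DegenerateInputError):
            build_ml_features(np.ones(100), np.ones(100), scale="zscore")

    def test_odd_target_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_ml_features(np.ones(10), np.ones(10), target_length=501)


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        report = evaluate_classifier(y, y, ["a", "b", "c"])
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        np.testing.assert_array_equal(report.confusion, 2 * np.eye(3, dtype=int))

    def test_binary_worked_example(self):
        # TP=8, FP=2, FN=2 for the positive class -> P = R = F1 = 0.8
        true = ["pos"] * 10 + ["neg"] * 10
        pred = ["pos"] * 8 + ["neg"] * 2 + ["pos"] * 2 + ["neg"] * 8
        report = evaluate_classifier(true, pred, ["pos", "neg"])
        i = report.class_order.index("pos")
        assert report.per_class_precision[i] == pytest.approx(0.8)
        assert report.per_class_recall[i] == pytest.approx(0.8)
        assert report.per_class_f1[i] == pytest.approx(0.8)

    def test_agrees_with_exhaustive_recount_on_random_labels(self):
        rng = np.random.default_rng(3)
        classes = [86.0, 113.0, 198.0]
        true = rng.choice(classes, size=200)
        pred = rng.choice(classes, size=200)
        report = evaluate_classifier(true, pred, classes)
        # brute-force recount over all (true, pred) pairs
        for i, c in enumerate(classes):
            tp = np.sum((true == c) & (pred == c))
            fp = np.sum((true != c) & (pred == c))
            fn = np.sum((true == c) & (pred != c))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            assert report.per_class_precision[i] == pytest.approx(p)
            assert report.per_class_recall[i] == pytest.approx(r)
            assert report.per_class_f1[i] == pytest.approx(f1)
        assert report.accuracy == pytest.approx(np.mean(true == pred))
        assert report.macro_f1 == pytest.approx(
            f1_score(true, pred, labels=classes, average="macro", zero_division=0)
        )

    def test_row_sums_and_trace_invariants(self):
        rng = np.random.default_rng(4)
        true = rng.integers(0, 4, 120)
        pred = rng.integers(0, 4, 120)
        report = evaluate_classifier(true, pred, [0, 1, 2, 3])
        assert report.confusion.sum() == 120
        for c in range(4):
            assert report.confusion[c].sum() == np.sum(true == c)
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum()
        )

    def test_empty_class_scores_zero(self):
        report = evaluate_classifier([0, 0], [1, 1], [0, 1, 2])
        assert report.per_class_f1[2] == 0.0
        assert report.macro_f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluate_classifier([0, 1], [0], [0, 1])


class TestStratifiedSplit:
    def test_preserves_class_proportions_within_one_sample(self):
        labels = np.repeat(np.arange(13), 10)
        train, test = stratified_split(labels, 0.7, seed=0)
        assert len(train) + len(test) == 130
        for c in range(13):
            assert np.sum(labels[train] == c) in (6, 7, 8)
            assert np.sum(labels[test] == c) in (2, 3, 4)
        assert set(train).isdisjoint(test)


def _blobs(n_per_class=50, k=2, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((n_per_class, 5)) + sep * i for i in range(k)]
    )
    y = np.repeat(np.arange(k), n_per_class)
    return FeatureMatrix(X, y)


class TestGlucoseSVM:
    def test_separable_blobs_reach_perfect_cv(self):
        res = train_svm(_blobs(), opt_budget=8, seed=0)
        assert res.cv_accuracy == 1.0
        assert res.fold_accuracies.min() == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(1)
        fm = _blobs(n_per_class=40, k=4, sep=0.0, seed=1)
        fm.labels = rng.permutation(fm.labels)
        res = train_svm(fm, opt_budget=8, seed=1)
        # binomial null: 1/K +- 3 sigma over 160 CV predictions
        p = 1.0 / 4.0
        sigma = np.sqrt(p * (1 - p) / 160)
        assert res.cv_accuracy < p + 3 * sigma + 0.05

    def test_search_deterministic_for_fixed_seed(self):
        fm = _blobs(n_per_class=20, sep=2.0, seed=2)
        a = train_svm(fm, opt_budget=6, seed=3)
        b = train_svm(fm, opt_budget=6, seed=3)
        assert a.best_params == b.best_params
        assert a.cv_accuracy == b.cv_accuracy

    def test_small_class_rejected(self):
        X = np.zeros((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(InvalidInputError):
            GlucoseSVM(X, y)
        with pytest.raises(InvalidInputError):
            GlucoseSVM(np.zeros((10, 3)), np.zeros(10))  # single class

    def test_predict_and_serialization(self, tmp_path):
        fm = _blobs(n_per_class=10, seed=4)
        res = train_svm(fm, opt_budget=6, seed=4)
        labels = predict(res, fm.X)
        assert set(labels) <= set(fm.labels)
        assert predict(res, np.empty((0, 5))).shape == (0,)
        with pytest.raises(InvalidInputError):
            predict(res, np.zeros((2, 7)))
        loaded = SVMResults.load(res.save(tmp_path / "svm.pkl"))
        np.testing.assert_array_equal(loaded.predict(fm.X), labels)
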
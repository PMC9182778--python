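from fractions import Fraction

import numpy as np
import pytest
import sklearn.metrics as skm

from skelwin.models_eval import (
    FALL,
    NOT_FALL,
    ConfusionCounts,
    Metrics,
    ProtocolConfig,
    collapse_to_binary,
    compute_metrics,
    confusion,
    confusion_matrix_table,
    multiclass_metrics,
    run_protocol,
)
from skelwin.windowing import FeatureMatrix


class TestCollapseToBinary:
    def test_fall_ids_map_to_positive(self):
        np.testing.assert_array_equal(collapse_to_binary([1, 3, 5]), [FALL] * 3)

    def test_daily_ids_map_to_negative(self):
        np.testing.assert_array_equal(collapse_to_binary([6, 11, 12]), [NOT_FALL] * 3)

    def test_mixed(self):
        np.testing.assert_array_equal(collapse_to_binary([2, 7]), [FALL, NOT_FALL])

    @pytest.mark.parametrize("bad", [[0], [13], [1, 20]])
    def test_out_of_vocabulary_rejected(self, bad):
        with pytest.raises(ValueError):
            collapse_to_binary(bad)


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1], positive=1)
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_identical_vectors_have_no_errors(self):
        c = confusion([1, 0, 1], [1, 0, 1], positive=1)
        assert c.fp == 0 and c.fn == 0

    def test_all_predicted_positive_on_negative_truth(self):
        c = confusion([0] * 5, [1] * 5, positive=1)
        assert (c.tp, c.fp) == (0, 5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1], positive=1)

    def test_counts_sum_to_n(self, rng):
        t = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        assert confusion(t, p, positive=1).total == 50


class TestComputeMetrics:
    def test_near_perfect_fall_recall(self):
        # 4425 fall windows of which 5 missed -> recall 99.89%
        m = compute_metrics(ConfusionCounts(tp=4420, fn=5, fp=100, tn=10000))
        assert m.recall == pytest.approx(99.89, abs=0.005)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(getattr(m, n) == 100.0 for n in
                   ("accuracy", "precision", "recall", "specificity", "f1"))

    def test_hand_computed_table(self):
        m = compute_metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5))
        assert m.precision == pytest.approx(80.00, abs=0.005)
        assert m.recall == pytest.approx(61.54, abs=0.005)
        assert m.accuracy == pytest.approx(93.00, abs=0.005)
        assert m.specificity == pytest.approx(97.70, abs=0.005)
        assert m.f1 == pytest.approx(69.57, abs=0.005)

    def test_zero_denominator_reported_as_zero(self, caplog):
        with caplog.at_level("WARNING"):
            m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert "undefined" in caplog.text

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_exact_rational_arithmetic(self, rng):
        def frac(num, den):
            return float(100 * Fraction(num, den)) if den else 0.0

        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fp + tn + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == frac(tp + tn, tp + fp + tn + fn)
            assert m.precision == frac(tp, tp + fp)
            assert m.recall == frac(tp, tp + fn)
            assert m.specificity == frac(tn, tn + fp)
            p, r = Fraction(m.precision), Fraction(m.recall)
            expected_f1 = float(2 * p * r / (p + r)) if p + r else 0.0
            assert m.f1 == pytest.approx(expected_f1, rel=1e-12)


class TestMulticlassMetrics:
    def test_perfect_prediction(self):
        m = multiclass_metrics([1, 2, 3], [1, 2, 3])
        assert m.accuracy == 100.0 and m.recall == 100.0

    def test_enumeration_oracle(self):
        t = [1, 1, 2, 2, 3, 3]
        p = [1, 1, 2, 2, 3, 2]
        m = multiclass_metrics(t, p)
        assert m.accuracy == pytest.approx(100 * 5 / 6)
        assert m.recall == pytest.approx((100 + 100 + 50) / 3)

    def test_single_class_truth(self):
        m = multiclass_metrics([4, 4], [4, 4], vocabulary=[4])
        assert m.accuracy == 100.0

    def test_class_absent_from_truth_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            m = multiclass_metrics([1, 1, 2], [1, 2, 2], vocabulary=[1, 2, 3])
        assert "absent" in caplog.text
        assert m.recall == pytest.approx((50 + 100) / 2)

    def test_accuracy_invariant_under_relabeling(self, rng):
        t = rng.integers(1, 6, 100)
        p = rng.integers(1, 6, 100)
        perm = {c: c_new for c, c_new in zip(range(1, 6), rng.permutation(range(1, 6)))}
        relabel = np.vectorize(perm.get)
        a = multiclass_metrics(t, p)
        b = multiclass_metrics(relabel(t), relabel(p))
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.recall == pytest.approx(b.recall)

    def test_agrees_with_sklearn_macro_averages(self, rng):
        # independent library oracle on cases without absent/unpredicted classes
        for _ in range(50):
            t = rng.integers(1, 5, 200)
            p = np.where(rng.random(200) < 0.7, t, rng.integers(1, 5, 200))
            if len(np.unique(p)) < 4 or len(np.unique(t)) < 4:
                continue
            m = multiclass_metrics(t, p)
            assert m.accuracy == pytest.approx(100 * skm.accuracy_score(t, p))
            assert m.recall == pytest.approx(100 * skm.recall_score(t, p, average="macro"))
            assert m.precision == pytest.approx(
                100 * skm.precision_score(t, p, average="macro")
            )


def gaussian_clusters(rng, n=400, gap=20.0, n_features=10):
    half = n // 2
    X = rng.normal(size=(n, n_features))
    X[half:] += gap
    y = np.concatenate([np.full(half, 6), np.full(half, 1)])
    return FeatureMatrix(values=X, labels=y)


class TestRunProtocol:
    def test_separable_clusters_are_perfect_every_round(self, rng):
        matrix = gaussian_clusters(rng)
        report = run_protocol(
            matrix, ProtocolConfig(model="knn", rounds=10, seed=3), task="binary"
        )
        assert all(m.accuracy == 100.0 for m in report.rounds)
        assert report.mean("recall") == 100.0

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        matrix = gaussian_clusters(rng)
        shuffled = FeatureMatrix(
            values=matrix.values, labels=rng.permutation(matrix.labels)
        )
        report = run_protocol(
            shuffled, ProtocolConfig(model="knn", rounds=10, seed=3), task="binary"
        )
        # permutation null: accuracy near the 50% majority rate, well below ceiling
        assert 35.0 < report.mean("accuracy") < 65.0

    @pytest.mark.parametrize("model", ["rf", "knn"])
    def test_identical_seeds_bit_reproducible(self, rng, model):
        matrix = gaussian_clusters(rng, n=120)
        cfg = ProtocolConfig(model=model, rounds=2, seed=11)
        a = run_protocol(matrix, cfg, task="binary")
        b = run_protocol(matrix, cfg, task="binary")
        assert [m.as_dict() for m in a.rounds] == [m.as_dict() for m in b.rounds]
        for ca, cb in zip(a.confusions, b.confusions):
            np.testing.assert_array_equal(ca, cb)

    def test_single_round_fixed_seed_deterministic(self, rng):
        matrix = gaussian_clusters(rng, n=100)
        cfg = ProtocolConfig(model="knn", rounds=1, seed=5)
        a = run_protocol(matrix, cfg, task="binary")
        b = run_protocol(matrix, cfg, task="binary")
        assert a.rounds[0] == b.rounds[0]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(model="lstm")

    def test_single_class_matrix_rejected(self, rng):
        matrix = FeatureMatrix(values=rng.normal(size=(10, 3)), labels=np.full(10, 7))
        with pytest.raises(ValueError):
            run_protocol(matrix, ProtocolConfig(model="knn", rounds=1), task="binary")

    def test_confusion_tables_partition_test_set(self, rng):
        matrix = gaussian_clusters(rng, n=100)
        report = run_protocol(
            matrix, ProtocolConfig(model="rf", rounds=3, seed=0), task="binary"
        )
        for table in report.confusions:
            assert table.sum() == 30  # 30% of 100


def test_group_splits_prevent_video_leakage(rng):
    """Features that only fingerprint the video: window-level splits look
    perfect, split-by-video collapses to chance."""
    n_videos, per_video = 8, 20
    video_class = np.array([1, 6] * (n_videos // 2))
    X = np.repeat(rng.normal(size=(n_videos, 5)) * 100, per_video, axis=0)
    X += rng.normal(scale=0.1, size=X.shape)
    y = np.repeat(video_class, per_video)
    groups = np.repeat(np.arange(n_videos), per_video)
    matrix = FeatureMatrix(values=X, labels=y)
    cfg = ProtocolConfig(model="knn", rounds=5, seed=2)
    leaky = run_protocol(matrix, cfg, task="binary")
    honest = run_protocol(matrix, cfg, task="binary", groups=groups)
    assert leaky.mean("accuracy") == 100.0
    assert honest.mean("accuracy") < 80.0


def test_confusion_matrix_table_counts(rng):
    t = [1, 1, 2, 3]
    p = [1, 2, 2, 3]
    mat = confusion_matrix_table(t, p, classes=[1, 2, 3])
    np.testing.assert_array_equal(mat, [[1, 1, 0], [0, 1, 0], [0, 0, 1]])


def test_metrics_report_summary_shape():
    rounds = [Metrics(100, 100, 100, 100, 100), Metrics(90, 90, 90, 90, 90)]
    from skelwin.models_eval import MetricsReport

    rep = MetricsReport(task="binary", model="rf", rounds=rounds)
    s = rep.summary()
    assert s["accuracy"]["mean"] == 95.0
    assert s["recall"]["sd"] == pytest.approx(np.std([100, 90], ddof=1))
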
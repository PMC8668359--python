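"""Evaluation protocol: splits, CV partitioning, metric identities and
the classifier zoo."""

import numpy as np
import pytest

from dermafuse import (
    ClassifierConfig,
    FeatureMatrix,
    SyntheticFeatureSpec,
    compute_metrics,
    cross_validate,
    make_synthetic_features,
    run_zoo,
    split_holdout,
)
from dermafuse.evaluate import ZOO_NAMES, make_classifier


def naive_metrics(cm):
    """Independent loop implementation of the metric suite."""
    cm = [[float(x) for x in row] for row in cm]
    k = len(cm)
    recalls, precisions = [], []
    for c in range(k):
        row = sum(cm[c])
        col = sum(cm[r][c] for r in range(k))
        recalls.append(cm[c][c] / row if row else 0.0)
        precisions.append(cm[c][c] / col if col else 0.0)
    r = 100 * sum(recalls) / k
    p = 100 * sum(precisions) / k
    total = sum(sum(row) for row in cm)
    acc = 100 * sum(cm[c][c] for c in range(k)) / total
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"recall_pct": r, "precision_pct": p, "fnr_pct": 100 - r,
            "accuracy_pct": acc, "f1_pct": f1}


@pytest.fixture(scope="module")
def separable():
    spec = SyntheticFeatureSpec(
        n_per_class=30, n_classes=3, d_informative=5, d_noise=5,
        separation=8.0, seed=13,
    )
    fm, y, _ = make_synthetic_features(spec)
    return fm


class TestHoldout:
    def test_70_30_stratified(self):
        spec = SyntheticFeatureSpec(25, 4, 3, 3, seed=0)
        fm, y, _ = make_synthetic_features(spec)
        train, test = split_holdout(fm, ratio=0.7, seed=1)
        assert train.n_samples == 70 and test.n_samples == 30
        for c in np.unique(fm.labels):
            assert abs((train.labels == c).sum() - 17.5) <= 1

    def test_partition_exact(self, separable):
        train, test = split_holdout(separable, seed=2)
        assert train.n_samples + test.n_samples == separable.n_samples

    def test_degenerate_ratio_rejected(self, separable):
        with pytest.raises(ValueError):
            split_holdout(separable, ratio=1.0)

    def test_seed_reproducible(self, separable):
        a = split_holdout(separable, seed=5)
        b = split_holdout(separable, seed=5)
        assert np.array_equal(a[0].values, b[0].values)

    def test_singleton_class_rejected(self):
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(5, 2)),
                           np.array([0, 0, 0, 0, 1]))
        with pytest.raises(ValueError):
            split_holdout(fm)


class TestMetrics:
    def test_perfect_confusion(self):
        m = compute_metrics(np.diag([5, 7, 9]))
        assert m["recall_pct"] == 100.0
        assert m["precision_pct"] == 100.0
        assert m["accuracy_pct"] == 100.0
        assert m["f1_pct"] == 100.0
        assert m["fnr_pct"] == 0.0

    def test_hand_computed_two_class_case(self):
        m = compute_metrics([[8, 2], [4, 6]])
        assert m["recall_pct"] == pytest.approx(70.0)
        assert m["accuracy_pct"] == pytest.approx(70.0)
        assert m["precision_pct"] == pytest.approx((800 / 12 + 75) / 2)
        assert m["fnr_pct"] == pytest.approx(30.0)

    def test_fnr_recall_identity_exact(self, rng):
        for _ in range(200):
            k = rng.integers(2, 6)
            cm = rng.integers(0, 30, size=(k, k))
            cm += np.eye(k, dtype=int)  # avoid empty rows
            m = compute_metrics(cm)
            assert m["fnr_pct"] + m["recall_pct"] == pytest.approx(100.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 7))
            cm = rng.integers(1, 50, size=(k, k))
            m = compute_metrics(cm)
            ref = naive_metrics(cm)
            for key, val in ref.items():
                assert m[key] == pytest.approx(val, abs=1e-9)

    def test_invalid_confusion_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            compute_metrics([[1, -2], [0, 3]])


class TestCrossValidate:
    def test_perfectly_separable_hits_ceiling(self, separable):
        row = cross_validate(separable, ClassifierConfig("LSVM"), k=5, seed=0)
        assert row.accuracy_pct == 100.0
        assert row.fnr_pct == 0.0
        assert row.auc == pytest.approx(1.0, abs=1e-6)

    def test_confusion_mass_conservation(self, separable):
        row = cross_validate(separable, ClassifierConfig("WKNN"), k=5, seed=0)
        assert row.confusion.sum() == separable.n_samples
        assert np.array_equal(row.confusion.sum(axis=1),
                              np.full(3, 30))

    def test_shuffled_labels_near_chance(self):
        spec = SyntheticFeatureSpec(30, 3, 4, 4, separation=6.0, seed=4)
        fm, y, _ = make_synthetic_features(spec)
        rng = np.random.default_rng(0)
        accs = []
        for s in range(5):
            shuffled = FeatureMatrix(fm.values, rng.permutation(fm.labels),
                                     list(fm.column_ids))
            accs.append(
                cross_validate(shuffled, ClassifierConfig("LSVM"), k=5,
                               seed=s).accuracy_pct
            )
        assert abs(np.mean(accs) - 100 / 3) < 12

    def test_fold_reduction_warning(self):
        spec = SyntheticFeatureSpec(5, 3, 3, 3, separation=5.0, seed=0)
        fm, _, _ = make_synthetic_features(spec)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(fm, ClassifierConfig("LSVM"), k=10, seed=0)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierConfig("SuperSVM")


class TestZoo:
    def test_all_ten_presets_instantiate(self):
        for name in ZOO_NAMES:
            assert make_classifier(ClassifierConfig(name)) is not None

    def test_full_zoo_beats_chance_on_separable(self, separable):
        report = run_zoo(separable, protocol="cv", k=5, seed=0)
        assert len(report.rows) == 10
        for row in report.rows:
            assert row.accuracy_pct > 100 / 3
        assert report.best.accuracy_pct == max(r.accuracy_pct for r in report.rows)

    def test_single_member_zoo(self, separable):
        report = run_zoo(separable, zoo=[ClassifierConfig("MGSVM")],
                         protocol="holdout", seed=1)
        assert len(report.rows) == 1
        assert report.protocol == "holdout"

    def test_reruns_identical(self, separable):
        a = run_zoo(separable, zoo=[ClassifierConfig("LSVM")], protocol="cv",
                    k=5, seed=7)
        b = run_zoo(separable, zoo=[ClassifierConfig("LSVM")], protocol="cv",
                    k=5, seed=7)
        assert np.array_equal(a.rows[0].confusion, b.rows[0].confusion)
        assert a.rows[0].accuracy_pct == b.rows[0].accuracy_pct

    def test_empty_zoo_rejected(self, separable):
        with pytest.raises(ValueError):
            run_zoo(separable, zoo=[])

    def test_duplicate_names_rejected(self, separable):
        with pytest.raises(ValueError, match="unique"):
            run_zoo(separable, zoo=[ClassifierConfig("LSVM"),
                                    ClassifierConfig("LSVM")])
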
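"""Skewness screening and the SVR-validated selection loop."""

import numpy as np
import pytest

from dermafuse import (
    FeatureMatrix,
    SelectionConfig,
    SkewnessSVRSelector,
    SyntheticFeatureSpec,
    make_synthetic_features,
    pearson_skewness,
    select_features,
    skew_threshold,
    svr_fitness,
)


def naive_skewness(v):
    """Loop-based oracle: 3 (mean - median) / sample SD."""
    v = sorted(float(x) for x in v)
    n = len(v)
    mean = sum(v) / n
    median = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2
    s = (sum((x - mean) ** 2 for x in v) / (n - 1)) ** 0.5
    return 3 * (mean - median) / s


def fm_of(values, labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.zeros(values.shape[0], dtype=int)
    return FeatureMatrix(values, labels)


class TestPearsonSkewness:
    def test_symmetric_vector_is_zero(self):
        assert pearson_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0)

    def test_hand_computed_right_skew(self):
        # mean 4, median 3, s = sqrt(50/4)
        assert pearson_skewness([1, 2, 3, 4, 10]) == pytest.approx(
            0.848528137423857
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_skewness([2.0, 2.0, 2.0])

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            v = rng.normal(size=rng.integers(3, 40))
            assert pearson_skewness(v) == pytest.approx(
                naive_skewness(v), abs=1e-9
            )


class TestSkewThreshold:
    def test_symmetric_means_candidates_nonnegative(self):
        # column means (1..5) symmetric -> skew 0 -> all means >= 0 kept
        X = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], (6, 1))
        cand, skew = skew_threshold(fm_of(X))
        assert skew == pytest.approx(0.0)
        assert cand.tolist() == [0, 1, 2, 3, 4]

    def test_hand_computed_all_candidates(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0, 10.0], (4, 1))
        cand, skew = skew_threshold(fm_of(X))
        assert skew == pytest.approx(0.848528137423857)
        assert cand.tolist() == [0, 1, 2, 3, 4]

    def test_hand_computed_single_candidate(self):
        X = np.tile([0.1, 0.2, 5.0], (4, 1))
        cand, skew = skew_threshold(fm_of(X))
        assert skew == pytest.approx(3 * (np.mean([0.1, 0.2, 5.0]) - 0.2)
                                     / np.std([0.1, 0.2, 5.0], ddof=1))
        assert cand.tolist() == [2]

    def test_degenerate_means_select_all_with_warning(self):
        X = np.ones((5, 4))
        with pytest.warns(UserWarning, match="column means equal"):
            cand, skew = skew_threshold(fm_of(X))
        assert cand.tolist() == [0, 1, 2, 3]
        assert skew == 0.0

    def test_partition_inequality_exact(self, rng):
        X = rng.normal(size=(25, 40))
        cand, skew = skew_threshold(fm_of(X))
        means = X.mean(axis=0)
        assert (means[cand] >= skew).all()
        out = np.setdiff1d(np.arange(40), cand)
        assert (means[out] < skew).all()


class TestSVRFitness:
    def test_separable_blobs_high_accuracy(self):
        accs = []
        for seed in range(10):
            spec = SyntheticFeatureSpec(
                n_per_class=50, n_classes=2, d_informative=4, d_noise=2,
                separation=10.0, seed=seed,
            )
            fm, y, _ = make_synthetic_features(spec)
            accs.append(svr_fitness(fm.values, y, SelectionConfig(seed=seed)))
        assert np.mean(accs) >= 0.95

    def test_permuted_labels_at_chance(self, rng):
        spec = SyntheticFeatureSpec(
            n_per_class=60, n_classes=2, d_informative=4, d_noise=2,
            separation=10.0, seed=0,
        )
        fm, y, _ = make_synthetic_features(spec)
        accs = [
            svr_fitness(fm.values, rng.permutation(y), SelectionConfig(seed=s))
            for s in range(10)
        ]
        # chance is 0.5; 10 x 36 held-out predictions give ~0.03 SE
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_pure_noise_column_at_chance(self, rng):
        X = rng.normal(size=(200, 1))
        y = np.repeat([0, 1], 100)
        accs = [svr_fitness(X, y, SelectionConfig(seed=s)) for s in range(10)]
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            svr_fitness(rng.normal(size=(10, 2)), np.zeros(10))


class TestSelectionLoop:
    def test_converges_on_separable_data(self):
        spec = SyntheticFeatureSpec(
            n_per_class=60, n_classes=2, d_informative=6, d_noise=4,
            separation=8.0, nonnegative=True, seed=21,
        )
        fm, y, informative = make_synthetic_features(spec)
        res = select_features(fm, cfg=SelectionConfig(seed=21))
        assert res.converged
        assert res.iterations_run == 1
        assert len(res.fitness_trace) == 1
        assert set(res.selected_idx) & informative

    def test_zero_target_converges_immediately(self, rng):
        fm = fm_of(rng.normal(size=(40, 6)),
                   labels=rng.integers(0, 2, size=40))
        res = select_features(fm, cfg=SelectionConfig(target_accuracy=0.0))
        assert res.converged and res.iterations_run == 1

    def test_inseparable_data_exhausts_iterations(self):
        spec = SyntheticFeatureSpec(
            n_per_class=40, n_classes=3, d_informative=4, d_noise=6,
            separation=0.0, seed=5,
        )
        fm, y, _ = make_synthetic_features(spec)
        res = select_features(fm, cfg=SelectionConfig(seed=5))
        assert not res.converged
        assert res.iterations_run == 5
        assert len(res.fitness_trace) == 5

    def test_candidate_sets_non_shrinking(self):
        """Relaxation can only admit columns, never drop them."""
        spec = SyntheticFeatureSpec(
            n_per_class=40, n_classes=3, d_informative=4, d_noise=6,
            separation=0.5, nonnegative=True, seed=7,
        )
        fm, y, _ = make_synthetic_features(spec)
        means = fm.values.mean(axis=0)
        _, skew = skew_threshold(fm)
        thr, sets = skew, []
        for _ in range(5):
            sets.append(set(np.nonzero(means >= thr)[0]))
            thr = thr * 0.8 if thr >= 0 else thr / 0.8
        for a, b in zip(sets, sets[1:]):
            assert a <= b

    def test_informative_columns_enriched(self):
        """Selected set is richer in informative columns than the base rate."""
        fracs = []
        for seed in range(20):
            spec = SyntheticFeatureSpec(
                n_per_class=100, n_classes=3, d_informative=8, d_noise=32,
                separation=3.0, nonnegative=True, seed=seed,
            )
            fm, y, informative = make_synthetic_features(spec)
            res = select_features(fm, cfg=SelectionConfig(seed=seed))
            if res.selected_idx.size:
                fracs.append(
                    len(set(res.selected_idx) & informative) / res.selected_idx.size
                )
        assert np.mean(fracs) > 8 / 40

    def test_sklearn_selector_interface(self, blob_features):
        fm, y, _ = blob_features
        sel = SkewnessSVRSelector(seed=3).fit(fm.values, y)
        out = sel.transform(fm.values)
        assert out.shape == (fm.n_samples, sel.selected_idx_.size)
        assert sel.iterations_run_ <= 5
        assert len(sel.fitness_trace_) == sel.iterations_run_

    def test_n_features_cap(self, blob_features):
        fm, y, _ = blob_features
        sel = SkewnessSVRSelector(seed=3, n_features_cap=4).fit(fm.values, y)
        assert sel.selected_idx_.size <= 4
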
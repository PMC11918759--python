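import numpy as np
import pytest

from fnirscad import baselines as bl
from fnirscad.synth import canonical_hrf


class TestFeatureExtraction:
    def test_full_montage_feature_count(self, rng):
        sample = rng.normal(size=(6, 246, 68))
        row = bl.extract_features(sample)
        assert row.shape == (2448,)

    def test_toy_montage_feature_count_scales(self, rng):
        assert bl.extract_features(rng.normal(size=(6, 50, 4))).shape == (144,)

    def test_constant_trace_statistics(self):
        sample = np.full((6, 100, 2), 3.0)
        table = bl.build_feature_table(sample[None])
        frame = table.to_frame()
        assert frame.at[0, "dHbO.ch01.mean"] == pytest.approx(3.0)
        assert frame.at[0, "dHbO.ch01.variance"] == 0.0
        assert frame.at[0, "dHbO.ch01.peak"] == pytest.approx(3.0)
        assert frame.at[0, "dHbO.ch01.time_to_peak"] == 0.0  # first-index tie-break

    def test_time_to_peak_matches_explicit_scan(self):
        fs = 8.138
        trace = canonical_hrf(fs, duration_s=30.0)
        sample = np.zeros((6, trace.size, 1))
        sample[0, :, 0] = trace
        row = bl.extract_features(sample, sampling_rate=fs)
        names = bl._feature_names(1)
        ttp = row[names.index("dHbO.ch01.time_to_peak")]
        expected_idx = max(range(trace.size), key=lambda i: trace[i])
        assert ttp == pytest.approx(expected_idx / fs)
        assert 5.5 < ttp < 6.5

    def test_names_decode_back_to_triples(self):
        names = bl._feature_names(68)
        assert len(set(names)) == 2448
        ind, ch, stat = bl.FeatureTable.decode_name(names[7])
        assert ind == "dHbO" and ch == 2 and stat == "variance"

    def test_nan_input_rejected(self):
        bad = np.zeros((6, 10, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            bl.extract_features(bad)


class TestZScore:
    def test_population_sigma_convention(self):
        train = np.array([[1.0], [3.0]])
        tr, te = bl.zscore_fit_apply(train, np.array([[2.0]]))
        np.testing.assert_allclose(tr[:, 0], [-1.0, 1.0])  # population sigma
        assert te[0, 0] == 0.0  # value at the training mean maps to 0

    def test_normalized_columns_standardized(self, rng):
        train = rng.normal(size=(20, 5)) * 3 + 7
        tr, _ = bl.zscore_fit_apply(train, train[:1])
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_features_map_to_zero(self):
        train = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.warns(UserWarning):
            tr, te = bl.zscore_fit_apply(train, np.array([[5.0, 1.0]]))
        assert np.all(tr[:, 0] == 0.0) and te[0, 0] == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            bl.zscore_fit_apply(np.ones((1, 3)), np.ones((1, 3)))


class TestFisherScore:
    def test_identical_classes_score_zero(self):
        x = np.tile(np.array([[1.0, 2.0]]), (6, 1))
        scores, _ = bl.fisher_score(x, np.array([0, 0, 0, 1, 1, 1]))
        np.testing.assert_array_equal(scores, 0.0)

    def test_separated_feature_ranks_first(self, rng):
        n = 20
        labels = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 5))
        x[:, 3] += labels * 10.0
        _, order = bl.fisher_score(x, labels)
        assert order[0] == 3

    def test_matches_hand_computation_on_toy_table(self):
        """Direct spreadsheet-style evaluation of the weighted between/within
        variance ratio on a 6-subject table."""
        x = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        mu, mu1, mu2 = x.mean(), 2.0, 8.0
        var1 = var2 = np.array([1.0, 0.0, 1.0]).mean() * 2 / 3 + 2 / 3  # population var of {1,2,3}
        expected = (3 * (mu1 - mu) ** 2 + 3 * (mu2 - mu) ** 2) / (3 * (2 / 3) + 3 * (2 / 3))
        scores, _ = bl.fisher_score(x, labels)
        assert scores[0] == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bl.fisher_score(np.ones((4, 2)), np.zeros(4))


class TestClassifiers:
    def _clusters(self, rng, sep=10.0, n=10):
        x = np.vstack(
            [rng.normal(size=(n, 4)), rng.normal(size=(n, 4)) + sep]
        )
        y = np.repeat([0, 1], n)
        return x, y

    def test_both_classifiers_fit_separated_clusters(self, rng):
        x, y = self._clusters(rng)
        for fit in (bl.train_slda, bl.train_rsvm):
            clf = fit(x, y)
            assert (clf.predict(x) == y).all()

    def test_duplicating_training_points_keeps_decisions(self, rng):
        x, y = self._clusters(rng)
        probe = rng.normal(size=(20, 4)) * 4 + 5
        a = bl.train_rsvm(x, y).predict(probe)
        b = bl.train_rsvm(np.vstack([x, x]), np.concatenate([y, y])).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_full_shrinkage_approaches_nearest_mean(self, rng):
        """With shrinkage -> 1 the LDA covariance is spherical, so decisions
        reduce to the nearest class mean on standardized features."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x, y = self._clusters(rng, sep=3.0)
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1.0)
        clf.fit(x, y)
        probe = rng.normal(size=(50, 4)) * 3 + 1.5
        mean0, mean1 = x[y == 0].mean(axis=0), x[y == 1].mean(axis=0)
        scale = np.sqrt(np.trace(np.cov(x.T, bias=False)) / 4)
        d0 = np.linalg.norm((probe - mean0), axis=1)
        d1 = np.linalg.norm((probe - mean1), axis=1)
        nearest = (d1 < d0).astype(int)
        np.testing.assert_array_equal(clf.predict(probe), nearest)


class TestSweep:
    def _table(self, rng, n=16, informative=True):
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 30))
        if informative:
            x[:, 0] += y * 8.0
        return x, y

    def test_perfect_feature_gives_perfect_n1_accuracy(self, rng):
        x, y = self._table(rng)
        res = bl.n_feature_accuracy_sweep(x, y, classifier="slda", n_max=5)
        assert res.accuracy_per_n[0] == 100.0
        assert res.best_accuracy == 100.0

    def test_matches_naive_nested_loop_reimplementation(self, rng):
        """The vectorized sweep agrees fold-for-fold with a brute-force
        nested-loop implementation."""
        x, y = self._table(rng, n=12)
        n_max = 4
        res = bl.n_feature_accuracy_sweep(x, y, classifier="rsvm", n_max=n_max)
        correct = np.zeros(n_max)
        for i in range(len(y)):
            tr_idx = [j for j in range(len(y)) if j != i]
            mu = x[tr_idx].mean(axis=0)
            sd = x[tr_idx].std(axis=0)
            sd[sd == 0] = 1.0
            tr = (x[tr_idx] - mu) / sd
            te = (x[i : i + 1] - mu) / sd
            scores, order = bl.fisher_score(tr, y[tr_idx])
            for n in range(1, n_max + 1):
                clf = bl.train_rsvm(tr[:, order[:n]], y[tr_idx])
                correct[n - 1] += int(clf.predict(te[:, order[:n]])[0] == y[i])
        np.testing.assert_allclose(res.accuracy_per_n, 100.0 * correct / len(y))

    def test_no_leakage_from_test_row(self, rng):
        """An extreme outlier as the held-out subject must not perturb the
        training-fold normalization statistics or ranking."""
        x, y = self._table(rng, n=12)
        x2 = x.copy()
        x2[0] = 1e6  # only the held-out row changes
        mask = np.ones(len(y), dtype=bool)
        mask[0] = False
        tr_a, _ = bl.zscore_fit_apply(x[mask], x[0])
        tr_b, _ = bl.zscore_fit_apply(x2[mask], x2[0])
        np.testing.assert_array_equal(tr_a, tr_b)
        _, oa = bl.fisher_score(tr_a, y[mask])
        _, ob = bl.fisher_score(tr_b, y[mask])
        np.testing.assert_array_equal(oa, ob)

    def test_shuffled_labels_stay_within_permutation_null(self, rng):
        """With labels randomly shuffled, the sweep's best accuracy is an
        optimistic maximum over N; compare against a small permutation
        distribution of the same statistic rather than plain chance."""
        x, _ = self._table(rng, n=12, informative=False)
        y = np.repeat([0, 1], 6)
        observed = bl.n_feature_accuracy_sweep(
            x, rng.permutation(y), classifier="slda", n_max=5
        ).best_accuracy
        null = [
            bl.n_feature_accuracy_sweep(
                x, rng.permutation(y), classifier="slda", n_max=5
            ).best_accuracy
            for _ in range(20)
        ]
        assert observed <= max(null) + 1e-9

    def test_nmax_exceeding_feature_count_rejected(self, rng):
        x, y = self._table(rng)
        with pytest.raises(ValueError):
            bl.n_feature_accuracy_sweep(x, y, n_max=1000)
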
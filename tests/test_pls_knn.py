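"""Scaling, PLS extraction, weighted KNN and the cross-validation protocol."""

import numpy as np
import pytest

from drspipe.band_selection import BandSet
from drspipe.pls_knn import (apply_scaling, confusion_metrics, cross_validate,
                             fit_pls, fit_scaling, increment_rule, knn_predict,
                             predicted_labels, project, select_n_components)
from drspipe.spectra import LabeledSpectraSet


def _labels(n):
    return np.array(["mucosa", "tumor"] * (n // 2), dtype=object)


class TestScaling:
    def test_symmetric_column(self):
        X = np.array([[0.0], [5.0], [10.0]])
        out = apply_scaling(X, fit_scaling(X))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.full(4, 3.0), np.arange(4.0)])
        out = apply_scaling(X, fit_scaling(X))
        assert np.all(out[:, 0] == 0.0)

    def test_random_matrix_attains_extremes(self):
        X = np.random.default_rng(0).random((20, 50))
        out = apply_scaling(X, fit_scaling(X))
        np.testing.assert_allclose(out.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)


class TestPLS:
    def test_first_weight_proportional_to_covariance(self):
        """Duplicate-implementation oracle: w1 ∝ Xcᵀyc for single-response PLS."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        labels = _labels(6)
        model = fit_pls(X, labels, 2)
        y = np.where(labels == "tumor", 1.0, -1.0)
        expected = (X - X.mean(0)).T @ (y - y.mean())
        w1 = model.weights[:, 0]
        cos = np.dot(w1, expected) / (np.linalg.norm(w1) * np.linalg.norm(expected))
        assert abs(abs(cos) - 1.0) < 1e-10

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        model = fit_pls(X, _labels(20), 4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(np.diag(G)))

    def test_full_rank_matches_ols_fit(self):
        """With k = rank, regressing y on the scores reproduces the OLS fit on X."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        labels = _labels(12)
        y = np.where(labels == "tumor", 1.0, -1.0)
        model = fit_pls(X, labels, 4)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        fit_ols = Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0]
        T = model.scores
        fit_pls_scores = T @ np.linalg.lstsq(T, yc, rcond=None)[0]
        np.testing.assert_allclose(fit_pls_scores, fit_ols, atol=1e-8)

    def test_excessive_components_raise(self):
        X = np.random.default_rng(4).normal(size=(4, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, _labels(4), 4)


class TestProject:
    def test_training_projection_reproduces_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 6))
        model = fit_pls(X, _labels(14), 3)
        np.testing.assert_allclose(project(model, X), model.scores, atol=1e-10)

    def test_column_mean_row_maps_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        model = fit_pls(X, _labels(10), 2)
        np.testing.assert_allclose(project(model, X.mean(0, keepdims=True)),
                                   0.0, atol=1e-12)

    def test_explicit_matrix_algebra(self):
        """Hand-checked: projection = (X − mean) @ rotations."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        model = fit_pls(X, _labels(8), 2)
        new = rng.normal(size=(3, 3))
        np.testing.assert_allclose(project(model, new),
                                   (new - model.x_mean) @ model.rotations,
                                   atol=1e-12)

    def test_column_mismatch_raises(self):
        X = np.random.default_rng(8).normal(size=(8, 3))
        model = fit_pls(X, _labels(8), 2)
        with pytest.raises(ValueError, match="column mismatch"):
            project(model, np.zeros((2, 5)))


class TestIncrementRule:
    @pytest.mark.parametrize("accs,expected", [
        ([70, 78, 81, 82, 82.5], 3),
        ([80, 80, 80, 80], 1),
        ([50, 60, 70, 80], 4),
    ])
    def test_rule_by_hand(self, accs, expected):
        assert increment_rule(accs, threshold=2.0) == expected

    def test_on_synthetic_scores(self, small_contrast_dataset):
        ds = small_contrast_dataset
        X = apply_scaling(ds.spectra, fit_scaling(ds.spectra))
        k = select_n_components(X, ds.labels, max_k=6, iterations=3, seed=0)
        assert 1 <= k <= 6


class TestKNN:
    def test_zero_distance_dominates(self):
        train = np.array([[0.0], [1.0], [3.0]])
        labels = np.array(["mucosa", "mucosa", "tumor"], dtype=object)
        post = knn_predict(train, labels, np.array([[3.0]]), k=3)
        assert post[0] == 1.0

    def test_hand_arithmetic_oracle(self):
        """weights 1/d² = 0.25, 1, 1 → posterior(tumor) = 1/2.25 ≈ 0.444."""
        train = np.array([[0.0], [1.0], [3.0]])
        labels = np.array(["mucosa", "mucosa", "tumor"], dtype=object)
        post = knn_predict(train, labels, np.array([[2.0]]), k=3)
        assert post[0] == pytest.approx(1.0 / 2.25)
        assert predicted_labels(post)[0] == "mucosa"

    def test_brute_force_equivalence(self):
        """Posterior equals exhaustive recomputation on random instances."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            n, d, k = 30, 4, 10
            train = rng.normal(size=(n, d))
            labels = np.array(rng.choice(["mucosa", "tumor"], n), dtype=object)
            q = rng.normal(size=(1, d))
            post = knn_predict(train, labels, q, k=k)[0]
            dist = np.sqrt(((train - q) ** 2).sum(axis=1))
            order = np.argsort(dist, kind="stable")[:k]
            w = 1.0 / dist[order] ** 2
            expected = np.sum(w[labels[order] == "tumor"]) / np.sum(w)
            assert post == pytest.approx(expected, rel=1e-10)

    def test_k_exceeding_train_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(np.zeros((3, 1)),
                        np.array(["mucosa"] * 3, dtype=object),
                        np.zeros((1, 1)), k=5)


class TestConfusionMetrics:
    def test_counting_example(self):
        true = np.array(["tumor"] * 10 + ["mucosa"] * 10, dtype=object)
        pred = np.array(["tumor"] * 8 + ["mucosa"] * 2
                        + ["mucosa"] * 9 + ["tumor"] * 1, dtype=object)
        post = np.where(pred == "tumor", 0.9, 0.1)
        m = confusion_metrics(true, pred, post)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_perfect_ranking_auc(self):
        true = np.array(["tumor"] * 5 + ["mucosa"] * 5, dtype=object)
        post = np.concatenate([np.linspace(0.6, 1.0, 5), np.linspace(0.0, 0.4, 5)])
        m = confusion_metrics(true, predicted_labels(post), post)
        assert m["auc"] == pytest.approx(1.0)

    def test_auc_matches_pairwise_count(self):
        """Mann–Whitney brute-force oracle over random score sets."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            n1, n0 = rng.integers(3, 15, 2)
            true = np.array(["tumor"] * n1 + ["mucosa"] * n0, dtype=object)
            post = rng.choice(np.linspace(0, 1, 7), n1 + n0)  # ties likely
            m = confusion_metrics(true, predicted_labels(post), post)
            pos, neg = post[:n1], post[n1:]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert m["auc"] == pytest.approx(wins / (n1 * n0), rel=1e-10)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion_metrics(np.array(["tumor"] * 4, dtype=object),
                              np.array(["tumor"] * 4, dtype=object),
                              np.ones(4))


class TestCrossValidate:
    def _blob_dataset(self, sep=8.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        wl = np.arange(500.0, 520.0, 1.0)
        X = rng.normal(size=(n, wl.size))
        labels = _labels(n)
        X[labels == "tumor"] += sep
        return LabeledSpectraSet(X, wl, labels,
                                 np.array(["P1"] * n, dtype=object))

    def test_separable_blobs_are_perfect(self):
        report = cross_validate(self._blob_dataset(), iterations=5, seed=1)
        assert report.accuracy[0] == pytest.approx(100.0)
        assert report.auc[0] == pytest.approx(1.0)
        assert report.accuracy[1] == 0.0

    def test_permuted_labels_give_chance_auc(self, small_contrast_dataset):
        ds = small_contrast_dataset
        rng = np.random.default_rng(2)
        shuffled = LabeledSpectraSet(ds.spectra, ds.wavelengths,
                                     rng.permutation(ds.labels),
                                     ds.patient_ids, ds.probe)
        report = cross_validate(shuffled, BandSet([(530.0, 590.0)]),
                                iterations=20, seed=3)
        assert 0.45 <= report.auc[0] <= 0.55

    def test_same_seed_reproduces_report(self, small_contrast_dataset):
        kw = dict(bands=BandSet([(530.0, 590.0)]), iterations=5, seed=11)
        r1 = cross_validate(small_contrast_dataset, **kw)
        r2 = cross_validate(small_contrast_dataset, **kw)
        assert r1.accuracy == r2.accuracy and r1.auc == r2.auc

    def test_row_order_invariance_of_pls_scores(self, small_contrast_dataset):
        """Scaling + PLS + projection do not depend on row order."""
        ds = small_contrast_dataset
        X = apply_scaling(ds.spectra, fit_scaling(ds.spectra))
        model = fit_pls(X, ds.labels, 4)
        perm = np.random.default_rng(13).permutation(ds.n_sites)
        Xp = apply_scaling(ds.spectra[perm], fit_scaling(ds.spectra[perm]))
        model_p = fit_pls(Xp, ds.labels[perm], 4)
        s1 = project(model, X[perm])
        s2 = model_p.scores
        # components are sign-indeterminate; compare up to per-column sign
        for c in range(4):
            assert (np.allclose(s1[:, c], s2[:, c], atol=1e-8)
                    or np.allclose(s1[:, c], -s2[:, c], atol=1e-8))

    def test_leakage_free_mode_runs(self, small_contrast_dataset):
        report = cross_validate(small_contrast_dataset,
                                BandSet([(530.0, 590.0)]),
                                iterations=3, seed=5, leakage_free=True)
        assert report.accuracy[0] > 60.0
        assert len(report.per_iteration) == 3
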
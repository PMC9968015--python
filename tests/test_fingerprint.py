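"""PCA, KNN classification, and per-day condition separability."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from optonose import (
    FingerprintDataset,
    classify_knn,
    condition_separability,
    fit_pca,
    project,
    read_fingerprints_csv,
    write_fingerprints_csv,
)


def _dataset(X, labels=None, days=None):
    labels = labels or ["x"] * X.shape[0]
    return FingerprintDataset(observations=X, labels=labels, days=days)


class TestDataset:
    def test_missing_entries_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            _dataset(X)

    def test_too_many_dye_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="at most 8"):
            _dataset(rng.uniform(0, 1, (3, 9)))


class TestPCA:
    def test_collinear_data_concentrates_variance_on_first_axis(self, rng):
        t = rng.uniform(-1, 1, 30)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer(t, direction) + 5
        model = fit_pca(_dataset(X))
        assert model.explained_variance_fractions[0] == pytest.approx(1.0)
        assert np.allclose(model.explained_variance_fractions[1:], 0, atol=1e-12)

    def test_fractions_sum_to_one(self, rng):
        model = fit_pca(_dataset(rng.normal(0, 1, (30, 8))))
        assert model.explained_variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.explained_variance_fractions) <= 1e-12)

    def test_fractions_match_covariance_eigenvalue_oracle(self, rng):
        X = rng.normal(0, 2, (30, 8))
        model = fit_pca(_dataset(X))
        # independent oracle: explicit covariance eigendecomposition
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.explained_variance_fractions, eigvals / eigvals.sum(), atol=1e-9)

    def test_loadings_orthonormal_and_sign_fixed(self, rng):
        model = fit_pca(_dataset(rng.normal(0, 1, (20, 5))))
        L = model.loadings
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_zero_variance_column_under_standardization_names_dye(self, rng):
        X = rng.normal(0, 1, (10, 3))
        X[:, 1] = 4.2
        data = FingerprintDataset(observations=X, labels=["x"] * 10, dyes=["a", "dead", "c"])
        with pytest.raises(ValueError, match="dead"):
            fit_pca(data, standardize=True)
        fit_pca(data, standardize=False)  # raw-covariance PCA is still fine

    def test_column_permutation_leaves_fractions_unchanged(self, rng):
        X = rng.normal(0, 1, (25, 6))
        perm = rng.permutation(6)
        f1 = fit_pca(_dataset(X)).explained_variance_fractions
        f2 = fit_pca(_dataset(X[:, perm])).explained_variance_fractions
        assert np.allclose(f1, f2, atol=1e-9)


class TestProjection:
    def test_center_point_projects_to_origin(self, rng):
        X = rng.normal(0, 1, (15, 4))
        model = fit_pca(_dataset(X))
        assert np.allclose(project(model, X.mean(axis=0)), 0, atol=1e-9)

    def test_score_variances_reproduce_fractions(self, rng):
        X = rng.normal(0, 3, (40, 5))
        model = fit_pca(_dataset(X))
        scores = project(model, X)
        var = scores.var(axis=0, ddof=1)
        assert np.allclose(var / var.sum(), model.explained_variance_fractions, atol=1e-9)

    def test_full_reconstruction_round_trip(self, rng):
        X = rng.normal(0, 1, (20, 6))
        model = fit_pca(_dataset(X))
        scores = project(model, X)
        back = scores @ model.loadings.T * model.column_scales + model.column_centers
        assert np.allclose(back, X, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_pca(_dataset(rng.normal(0, 1, (10, 4))))
        with pytest.raises(ValueError, match="columns"):
            project(model, rng.normal(0, 1, (3, 5)))


class TestKNN:
    def test_query_equal_to_training_point(self, rng):
        X = rng.normal(0, 1, (10, 3))
        labels = [f"c{i % 3}" for i in range(10)]
        train = FingerprintDataset(observations=X, labels=labels)
        assert classify_knn(train, X[4], k=1) == [labels[4]]

    def test_separated_gaussian_clusters_classified_perfectly(self, rng):
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 1.0, (20, 3)) for c in centers])
        labels = [lab for lab in "abc" for _ in range(20)]
        Q = np.vstack([c + rng.normal(0, 1.0, (10, 3)) for c in centers])
        expect = [lab for lab in "abc" for _ in range(10)]
        train = FingerprintDataset(observations=X, labels=labels)
        assert classify_knn(train, Q, k=3) == expect

    def test_k_equal_to_training_size_gives_global_majority(self, rng):
        X = rng.normal(0, 1, (9, 2))
        labels = ["maj"] * 5 + ["min"] * 4
        train = FingerprintDataset(observations=X, labels=labels)
        assert classify_knn(train, rng.normal(0, 1, (5, 2)), k=9) == ["maj"] * 5

    def test_vote_tie_breaks_to_nearest_neighbour(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        train = FingerprintDataset(observations=X, labels=["a", "a", "b", "b"])
        assert classify_knn(train, np.array([[4.0]]), k=4) == ["a"]
        assert classify_knn(train, np.array([[8.0]]), k=4) == ["b"]

    def test_matches_sklearn_on_unambiguous_data(self, rng):
        X = rng.normal(0, 1, (30, 4))
        labels = [f"c{i % 3}" for i in range(30)]
        Q = rng.normal(0, 1, (15, 4))
        train = FingerprintDataset(observations=X, labels=labels)
        sk = KNeighborsClassifier(n_neighbors=1).fit(X, labels)
        assert classify_knn(train, Q, k=1) == list(sk.predict(Q))

    def test_invariant_under_isometry(self, rng):
        X = rng.normal(0, 1, (20, 4))
        labels = [f"c{i % 2}" for i in range(20)]
        Q = rng.normal(0, 1, (8, 4))
        rot, _ = np.linalg.qr(rng.normal(0, 1, (4, 4)))
        shift = rng.normal(0, 5, 4)
        a = classify_knn(FingerprintDataset(observations=X, labels=labels), Q, k=3)
        b = classify_knn(
            FingerprintDataset(observations=X @ rot + shift, labels=labels), Q @ rot + shift, k=3
        )
        assert a == b

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            classify_knn(FingerprintDataset(np.zeros((1, 2)), ["x"]), np.zeros((1, 2)), k=2)


def _timecourse(rng, offsets_by_day, n_rep=3, sd=1.0):
    """Three conditions whose means sit at offsets_by_day[day] * condition index."""
    rows, labels, days = [], [], []
    for day, off in offsets_by_day.items():
        for ci, cond in enumerate(["control", "salt", "starve"]):
            mean = np.zeros(4) + ci * off
            for _ in range(n_rep):
                rows.append(mean + rng.normal(0, sd, 4))
                labels.append(cond)
                days.append(day)
    return FingerprintDataset(observations=np.vstack(rows), labels=labels, days=np.array(days))


class TestSeparability:
    def test_divergence_from_day_two_detected(self, rng):
        data = _timecourse(rng, {1: 0.0, 2: 10.0, 3: 10.0})
        report = condition_separability(data, standardize=False)
        assert report.separable_days == [2, 3]
        assert report.earliest_separable_day == 2

    def test_identical_conditions_score_near_chance(self):
        accs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            data = _timecourse(rng, {1: 0.0})
            report = condition_separability(data, standardize=False)
            accs.append(report.days[0].loo_accuracy)
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.12)

    def test_single_condition_day_skipped_with_note(self, rng):
        X = rng.normal(0, 1, (4, 3))
        data = FingerprintDataset(
            observations=X, labels=["only"] * 4, days=np.array([1, 1, 1, 1])
        )
        report = condition_separability(data)
        assert report.days == []
        assert any("only one condition" in n for n in report.notes)

    def test_label_shuffled_null_rarely_flags(self, rng):
        flags = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            data = _timecourse(r, {1: 10.0})
            labels = np.array(data.labels)
            data.labels = labels[r.permutation(len(labels))].tolist()
            report = condition_separability(data, standardize=False)
            flags += len(report.separable_days)
        assert flags / 30 <= 0.05


def test_fingerprint_csv_round_trip(tmp_path, rng):
    data = FingerprintDataset(
        observations=rng.uniform(0, 40, (6, 4)),
        labels=["a", "a", "b", "b", "c", "c"],
        dyes=["d1", "d2", "d3", "d4"],
        days=np.array([1, 1, 2, 2, 3, 3]),
    )
    path = tmp_path / "fp.csv"
    write_fingerprints_csv(data, path)
    back = read_fingerprints_csv(path)
    assert back.labels == data.labels and back.dyes == data.dyes
    assert np.array_equal(back.days, data.days)
    assert np.array_equal(back.observations, data.observations)
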
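"""Standardization, PCA, EM Gaussian mixture and shift-redundancy detection."""

import numpy as np
import pytest

from helixvar.geometry import extract_octapeptides, invariant_matrix
from helixvar.subclass_model import (
    assign,
    detect_shift_redundancy,
    fit_gmm,
    fit_pca,
    fit_standardizer,
    load_model,
    save_model,
)
from helixvar.synthetic import (
    DEFAULT_GEOMETRY_SPECS,
    SubclassGeometrySpec,
    generate_geometry,
)


class TestStandardizer:
    def test_transform_centers_and_scales(self, rng):
        X = rng.normal(loc=5, scale=3, size=(200, 7))
        std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_round_trip(self, rng):
        X = rng.normal(size=(50, 4))
        std = fit_standardizer(X)
        np.testing.assert_allclose(std.inverse_transform(std.transform(X)), X,
                                   atol=1e-10)

    def test_constant_column_guarded(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 1] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z[:, 1], 0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((1, 3)))


class TestPCA:
    def _six_signal_data(self, rng, n=3000, p=29):
        # 6 orthonormal loadings, equal signal variances, isotropic noise
        # sized so exactly 6 components are needed to reach 80% variance
        basis = np.linalg.qr(rng.normal(size=(p, p)))[0][:, :6]
        scores = rng.normal(scale=2.0, size=(n, 6))
        noise = rng.normal(scale=0.42, size=(n, p))
        return scores @ basis.T + noise

    def test_component_count_from_variance_threshold(self, rng):
        Z = self._six_signal_data(rng)
        # independent oracle: eigendecomposition of the covariance matrix
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        frac = evals / evals.sum()
        s_expected = int(np.searchsorted(np.cumsum(frac), 0.80) + 1)
        assert s_expected == 6  # fixture sanity
        assert fit_pca(Z, 0.80).s == 6

    def test_full_threshold_gives_rank(self, rng):
        low_rank = rng.normal(size=(100, 3)) @ rng.normal(size=(3, 10))
        assert fit_pca(low_rank, 1.0).s == 3

    def test_loadings_match_eigendecomposition(self, rng):
        Z = rng.normal(size=(500, 8))
        Z -= Z.mean(axis=0)
        model = fit_pca(Z, 0.9)
        evals, evecs = np.linalg.eigh(np.cov(Z.T, ddof=1))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for j in range(model.loadings.shape[1]):
            dot = abs(np.dot(model.loadings[:, j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_reconstruction(self, rng):
        Z = rng.normal(size=(120, 12))
        Z -= Z.mean(axis=0)
        model = fit_pca(Z, 1.0)
        Y = model.project(Z, n_components=12)
        np.testing.assert_allclose(model.reconstruct(Y), Z, atol=1e-8)

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 3)), 0.0)


class TestGMM:
    def _two_clusters(self, rng, n=10000, w0=0.7):
        n0 = int(n * w0)
        a = rng.normal(loc=[0, 0], scale=1.0, size=(n0, 2))
        b = rng.normal(loc=[10, 0], scale=1.0, size=(n - n0, 2))
        X = np.vstack([a, b])
        labels = np.r_[np.zeros(n0), np.ones(n - n0)]
        perm = rng.permutation(n)
        return X[perm], labels[perm]

    def test_two_cluster_parameter_recovery(self, rng):
        Y, _ = self._two_clusters(rng)
        model = fit_gmm(Y, k=2, seed=0)
        w = np.sort(model.weights)
        assert w[0] == pytest.approx(0.3, abs=0.02)
        means = model.means[np.argsort(model.means[:, 0])]
        assert np.linalg.norm(means[0] - [0, 0]) < 0.1
        assert np.linalg.norm(means[1] - [10, 0]) < 0.1

    def test_two_cluster_label_agreement(self, rng):
        from sklearn.metrics import adjusted_rand_score

        Y, labels = self._two_clusters(rng)
        model = fit_gmm(Y, k=2, seed=0)
        pred = np.argmax(model.predict_proba(Y), axis=1)
        assert adjusted_rand_score(labels, pred) >= 0.99

    def test_k1_closed_form(self, rng):
        Y = rng.normal(size=(300, 3))
        model = fit_gmm(Y, k=1, seed=0)
        np.testing.assert_allclose(model.means[0], Y.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            model.covariances[0], np.cov(Y.T, ddof=0) + 1e-6 * np.eye(3),
            atol=1e-7)

    def test_seeded_determinism(self, rng):
        Y, _ = self._two_clusters(rng, n=1000)
        a = fit_gmm(Y, k=2, seed=3)
        b = fit_gmm(Y, k=2, seed=3)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.means, b.means)

    def test_log_likelihood_monotone(self, rng):
        Y, _ = self._two_clusters(rng, n=2000)
        model = fit_gmm(Y, k=3, seed=1)
        diffs = np.diff(model.log_likelihood_trace)
        assert np.all(diffs >= -1e-6 * np.abs(model.log_likelihood_trace[:-1]))

    def test_matches_sklearn_mixture(self, rng):
        # independent EM implementation as cross-check on an easy problem
        from sklearn.mixture import GaussianMixture

        Y, _ = self._two_clusters(rng, n=4000)
        ours = fit_gmm(Y, k=2, seed=0)
        ref = GaussianMixture(2, covariance_type="full", random_state=0,
                              n_init=3).fit(Y)
        np.testing.assert_allclose(np.sort(ours.weights),
                                   np.sort(ref.weights_), atol=0.01)
        np.testing.assert_allclose(
            ours.means[np.argsort(ours.means[:, 0])],
            ref.means_[np.argsort(ref.means_[:, 0])], atol=0.05)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gmm(rng.normal(size=(5, 3)), k=2)


class TestAssign:
    def test_point_at_component_mean_wins(self, rng):
        Y, _ = self._fixture(rng)
        model = fit_gmm(Y, k=2, seed=0)
        for j in range(2):
            a = assign(model, model.means[j])
            assert a.subclass_id == j

    def _fixture(self, rng):
        n0 = 500
        a = rng.normal(loc=[0, 0], size=(n0, 2))
        b = rng.normal(loc=[10, 0], size=(n0, 2))
        return np.vstack([a, b]), None

    def test_posteriors_sum_to_one(self, rng):
        Y, _ = self._fixture(rng)
        model = fit_gmm(Y, k=2, seed=0)
        for y in rng.normal(scale=5, size=(20, 2)):
            a = assign(model, y)
            assert a.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert a.subclass_id == int(np.argmax(a.posterior))


class TestShiftRedundancy:
    @pytest.fixture(scope="class")
    def kink_shift_data(self):
        def windows(spec, n, seed0):
            return invariant_matrix(
                extract_octapeptides(generate_geometry(spec, 8, seed=seed0 + i))[0]
                for i in range(n))

        k4 = SubclassGeometrySpec(name="k4", kink_angle=25, kink_position=4)
        k5 = SubclassGeometrySpec(name="k5", kink_angle=25, kink_position=5)
        X = np.vstack([
            windows(k4, 80, 0),
            windows(k5, 80, 1000),
            windows(DEFAULT_GEOMETRY_SPECS["regular"], 80, 2000),
            windows(DEFAULT_GEOMETRY_SPECS["curved"], 80, 3000),
        ])
        labels = ["kink4"] * 80 + ["kink5"] * 80 + ["regular"] * 80 + ["curved"] * 80
        return labels, X

    def test_same_kink_at_shifted_positions_grouped(self, kink_shift_data):
        labels, X = kink_shift_data
        groups = detect_shift_redundancy(labels, X)
        merged = next(g for g in groups if "kink4" in g.members)
        assert set(merged.members) == {"kink4", "kink5"}
        (shift, corr), = merged.pair_stats.values()
        assert abs(shift) == 1
        assert corr >= 0.95

    def test_distinct_subclasses_not_grouped(self, kink_shift_data):
        labels, X = kink_shift_data
        groups = detect_shift_redundancy(labels, X)
        for g in groups:
            assert not ({"regular", "curved"} & set(g.members)
                        and len(g.members) > 1)

    def test_identical_subclass_self_correlation(self, kink_shift_data):
        labels, X = kink_shift_data
        # duplicate the regular class under a second name
        mask = np.array(labels) == "regular"
        X2 = np.vstack([X, X[mask]])
        labels2 = list(labels) + ["regular_copy"] * int(mask.sum())
        groups = detect_shift_redundancy(labels2, X2)
        merged = next(g for g in groups if "regular" in g.members)
        assert set(merged.members) == {"regular", "regular_copy"}
        (shift, corr), = merged.pair_stats.values()
        assert shift == 0
        assert corr == pytest.approx(1.0, abs=1e-9)

    def test_small_subclasses_excluded_with_warning(self, kink_shift_data):
        labels, X = kink_shift_data
        labels2 = list(labels)
        labels2[0] = "tiny"
        with pytest.warns(UserWarning, match="excluded"):
            groups = detect_shift_redundancy(labels2, X)
        assert all("tiny" not in g.members for g in groups)


def test_model_archive_round_trip(tmp_path, rng):
    X = rng.normal(size=(200, 29))
    std = fit_standardizer(X)
    pca = fit_pca(std.transform(X), 0.8)
    gmm = fit_gmm(pca.project(std.transform(X)), k=2, seed=0)
    path = tmp_path / "model.npz"
    save_model(path, std, pca, gmm)
    std2, pca2, gmm2 = load_model(path)
    np.testing.assert_array_equal(std.mean, std2.mean)
    np.testing.assert_array_equal(pca.loadings, pca2.loadings)
    assert pca2.s == pca.s
    np.testing.assert_array_equal(gmm.weights, gmm2.weights)
    y = rng.normal(size=pca.s)
    np.testing.assert_allclose(gmm.predict_proba(y[None, :]),
                               gmm2.predict_proba(y[None, :]), atol=1e-12)
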
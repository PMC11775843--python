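import numpy as np
import pytest
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
)
from sklearn.mixture import GaussianMixture

from endotyper.clustering import (
    MixtureParams,
    calinski_harabasz,
    davies_bouldin,
    fit_gmm,
    fit_kmeans,
    hard_labels,
    posterior_probs,
    select_k,
)
from endotyper.errors import ConfigError, DataError, DegenerateDataError


def planted_gaussians(means, n_per, seed=0, sd=0.5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(m, sd, size=(n_per, len(m))) for m in means])
    labels = np.repeat(np.arange(len(means)), n_per)
    return X, labels


class TestFitGMM:
    def test_two_separated_components_recovered(self):
        means = [(-3.0, 0.0), (3.0, 0.0)]
        X, _ = planted_gaussians(means, 10_000, seed=1)
        fit = fit_gmm(X, 2, seed=0)
        order = np.argsort(fit.params.means[:, 0])
        np.testing.assert_allclose(fit.params.means[order], means, atol=0.1)
        np.testing.assert_allclose(fit.params.weights, [0.5, 0.5], atol=0.02)

    def test_k1_closed_form(self):
        X, _ = planted_gaussians([(0.0, 0.0)], 2000, seed=2)
        fit = fit_gmm(X, 1, seed=0)
        np.testing.assert_allclose(fit.params.means[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(
            fit.params.covariances[0], np.cov(X, rowvar=False, ddof=0), atol=1e-4
        )

    def test_loglik_trace_monotone(self):
        X, _ = planted_gaussians([(-2, 0), (2, 0), (0, 3)], 500, seed=3)
        fit = fit_gmm(X, 3, seed=1)
        assert np.all(np.diff(fit.trace) >= -1e-8)

    def test_deterministic(self):
        X, _ = planted_gaussians([(-2, 0), (2, 0)], 500, seed=4)
        a = fit_gmm(X, 2, seed=5)
        b = fit_gmm(X, 2, seed=5)
        np.testing.assert_array_equal(a.params.means, b.params.means)

    def test_agrees_with_sklearn(self):
        # independent EM implementation cross-check on an easy instance
        X, _ = planted_gaussians([(-3, 0), (3, 0)], 5000, seed=6)
        fit = fit_gmm(X, 2, seed=0)
        sk = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0).fit(X)
        order_mine = np.argsort(fit.params.means[:, 0])
        order_sk = np.argsort(sk.means_[:, 0])
        np.testing.assert_allclose(
            fit.params.means[order_mine], sk.means_[order_sk], atol=0.05
        )
        np.testing.assert_allclose(
            fit.params.covariances[order_mine], sk.covariances_[order_sk], atol=0.05
        )

    def test_k_out_of_range_rejected(self):
        X, _ = planted_gaussians([(0, 0)], 100, seed=0)
        with pytest.raises(ConfigError):
            fit_gmm(X, 0, seed=0)
        with pytest.raises(ConfigError):
            fit_gmm(X, 50, seed=0)


class TestPosterior:
    def test_midpoint_symmetry(self):
        params = MixtureParams(
            weights=[0.5, 0.5],
            means=[[-1.0, 0.0], [1.0, 0.0]],
            covariances=[np.eye(2), np.eye(2)],
        )
        np.testing.assert_allclose(posterior_probs(params, [[0.0, 0.0]]), [[0.5, 0.5]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        params = MixtureParams(
            weights=[0.2, 0.3, 0.5],
            means=rng.normal(size=(3, 2)),
            covariances=np.array([np.eye(2)] * 3) * [[0.5], [1.0], [2.0]][0],
        )
        P = posterior_probs(params, rng.normal(size=(200, 2)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((P >= 0) & (P <= 1))

    def test_point_at_far_component_mean(self):
        params = MixtureParams(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0], [10.0, 0.0]],
            covariances=[np.eye(2), np.eye(2)],
        )
        P = posterior_probs(params, [[0.0, 0.0]])
        assert P[0, 0] > 0.99


class TestValidityIndices:
    def test_calinski_harabasz_hand_value(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        labels = [0, 0, 1, 1]
        # B=100, W=1: (100/1) / (1/2) = 200
        assert calinski_harabasz(x, labels) == pytest.approx(200.0)

    def test_davies_bouldin_hand_value(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        labels = [0, 0, 1, 1]
        # s=(0.5, 0.5), d=10: mean of (0.1, 0.1) = 0.1
        assert davies_bouldin(x, labels) == pytest.approx(0.1)

    def test_single_cluster_rejected(self):
        with pytest.raises(DegenerateDataError):
            calinski_harabasz(np.arange(4.0), [0, 0, 0, 0])
        with pytest.raises(DegenerateDataError):
            davies_bouldin(np.arange(4.0), [1, 1, 1, 1])

    def test_zero_within_dispersion_rejected(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        with pytest.raises(DegenerateDataError):
            calinski_harabasz(x, [0, 0, 1, 1])

    def test_coincident_centroids_rejected(self):
        x = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        with pytest.raises(DegenerateDataError):
            davies_bouldin(x, [0, 0, 1, 1])

    def test_translation_invariance(self):
        X, labels = planted_gaussians([(0, 0), (4, 1)], 100, seed=7)
        a = calinski_harabasz(X, labels)
        b = calinski_harabasz(X + 123.4, labels)
        assert a == pytest.approx(b)

    def test_duplication_invariance_db(self):
        X, labels = planted_gaussians([(0, 0), (4, 1)], 100, seed=8)
        a = davies_bouldin(X, labels)
        b = davies_bouldin(np.vstack([X, X]), np.concatenate([labels, labels]))
        assert a == pytest.approx(b)

    def test_agreement_with_sklearn_on_random_instances(self):
        """Both index formulas match sklearn's independent implementation on
        100 random small instances."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(10, 50))
            d = int(rng.integers(1, 4))
            k = int(rng.integers(2, min(5, n - 1)))
            X = rng.normal(size=(n, d))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz(X, labels) == pytest.approx(
                calinski_harabasz_score(X, labels), rel=1e-9
            )
            assert davies_bouldin(X, labels) == pytest.approx(
                davies_bouldin_score(X, labels), rel=1e-9
            )


class TestSelectK:
    @pytest.mark.parametrize("n_planted", [2, 3, 4])
    def test_recovers_planted_component_count(self, n_planted):
        centers = [(0, 0), (6, 0), (0, 6), (6, 6)][:n_planted]
        X, _ = planted_gaussians(centers, 1500, seed=n_planted, sd=0.7)
        res = select_k(X, range(2, 7), seed=0)
        assert res.selected_k == n_planted
        assert res.agreement

    def test_k_range_validated(self):
        X, _ = planted_gaussians([(0, 0)], 500, seed=0)
        with pytest.raises(ConfigError):
            select_k(X, range(1, 5))

    def test_table_one_row_per_k(self):
        X, _ = planted_gaussians([(0, 0), (5, 5)], 500, seed=1)
        res = select_k(X, range(2, 5), seed=0)
        assert res.table["k"].tolist() == [2, 3, 4]


class TestKMeans:
    def test_agrees_with_gmm_on_separated_data(self):
        X, _ = planted_gaussians([(-3, 0), (3, 0)], 5000, seed=10)
        gmm = fit_gmm(X, 2, seed=0)
        glab = hard_labels(gmm.params, X)
        klab, _ = fit_kmeans(X, 2, seed=0)
        assert adjusted_rand_score(glab, klab) > 0.9

    def test_k1_centroid_is_mean(self):
        X, _ = planted_gaussians([(1, 2)], 300, seed=11)
        labels, cents = fit_kmeans(X, 1, seed=0)
        np.testing.assert_allclose(cents[0], X.mean(axis=0), atol=1e-9)
        assert np.all(labels == 0)


class TestMixtureParams:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(DataError):
            MixtureParams([0.5, 0.6], [[0.0], [1.0]], [np.eye(1), np.eye(1)])

    def test_covariance_must_be_pd(self):
        with pytest.raises(DataError):
            MixtureParams([1.0], [[0.0, 0.0]], [np.array([[1.0, 2.0], [2.0, 1.0]])])

    def test_round_trip(self):
        p = MixtureParams([0.4, 0.6], [[0.0, 1.0], [2.0, 3.0]], [np.eye(2), 2 * np.eye(2)])
        q = MixtureParams.from_dict(p.to_dict())
        np.testing.assert_array_equal(p.means, q.means)
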
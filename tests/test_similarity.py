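import numpy as np
import pytest

from endotyper.errors import DegenerateDataError, InsufficientDataError
from endotyper.similarity import (
    EndotypeGaussian,
    fit_endotype_gaussian,
    kl_gaussian,
    similarity_matrix,
)
from endotyper.synth import DEVELOPMENT_SPECS, ENDOTYPE_NAMES, sample_endotype_points


def gauss(name, mean, cov):
    return EndotypeGaussian(name=name, mean=np.atleast_1d(mean), cov=np.atleast_2d(cov))


class TestKLGaussian:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = int(rng.integers(1, 5))
            A = rng.normal(size=(d, d))
            cov = A @ A.T + np.eye(d)
            P = gauss("p", rng.normal(size=d), cov)
            assert kl_gaussian(P, P) == pytest.approx(0.0, abs=1e-9)

    def test_unit_shift_one_dimensional(self):
        # KL(N(0,1) || N(1,1)) = 1/2
        P = gauss("p", 0.0, 1.0)
        Q = gauss("q", 1.0, 1.0)
        assert kl_gaussian(P, Q) == pytest.approx(0.5)

    def test_variance_four_one_dimensional(self):
        # KL(N(0,1) || N(0,4)) = 0.5*(1/4 - 1 + ln 4)
        P = gauss("p", 0.0, 1.0)
        Q = gauss("q", 0.0, 4.0)
        assert kl_gaussian(P, Q) == pytest.approx(0.5 * (0.25 - 1 + np.log(4)))

    def test_asymmetry(self):
        P = gauss("p", 0.0, 1.0)
        Q = gauss("q", 0.0, 4.0)
        assert kl_gaussian(P, Q) != pytest.approx(kl_gaussian(Q, P))

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = int(rng.integers(1, 5))
            A, B = rng.normal(size=(2, d, d))
            P = gauss("p", rng.normal(size=d), A @ A.T + np.eye(d))
            Q = gauss("q", rng.normal(size=d), B @ B.T + np.eye(d))
            assert kl_gaussian(P, Q) >= 0

    @pytest.mark.parametrize("d", [2, 4])
    def test_matches_monte_carlo(self, d):
        """Closed form within 2% of a 200k-sample Monte-Carlo estimate."""
        rng = np.random.default_rng(d)
        A, B = rng.normal(size=(2, d, d))
        P = gauss("p", rng.normal(size=d), A @ A.T + np.eye(d))
        Q = gauss("q", rng.normal(size=d), B @ B.T + np.eye(d))
        from scipy.stats import multivariate_normal

        x = rng.multivariate_normal(P.mean, P.cov, size=200_000)
        mc = np.mean(
            multivariate_normal.logpdf(x, P.mean, P.cov)
            - multivariate_normal.logpdf(x, Q.mean, Q.cov)
        )
        assert kl_gaussian(P, Q) == pytest.approx(mc, rel=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DegenerateDataError):
            kl_gaussian(gauss("p", 0.0, 1.0), gauss("q", [0.0, 0.0], np.eye(2)))


class TestFitEndotypeGaussian:
    def test_mean_equals_sample_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4))
        labels = np.array(["a"] * 100)
        g = fit_endotype_gaussian(X, labels, "a")
        np.testing.assert_allclose(g.mean, X.mean(axis=0))

    def test_too_few_points_rejected(self):
        X = np.zeros((9, 4))
        with pytest.raises(InsufficientDataError):
            fit_endotype_gaussian(X, np.array(["a"] * 9), "a")

    def test_identical_points_rejected(self):
        X = np.ones((50, 4))
        with pytest.raises(DegenerateDataError):
            fit_endotype_gaussian(X, np.array(["a"] * 50), "a")

    def test_recovers_generating_spec(self):
        spec = DEVELOPMENT_SPECS[2]
        n = 20_000
        X = sample_endotype_points(spec, n, seed=3)
        g = fit_endotype_gaussian(X, np.array([spec.name] * n), spec.name)
        se = spec.sd / np.sqrt(n)
        assert np.all(np.abs(g.mean - spec.mean) < 3 * se)


class TestSimilarityMatrix:
    def _gaussians(self, seed, scale=1.0):
        rng = np.random.default_rng(seed)
        out = {}
        for i, name in enumerate(ENDOTYPE_NAMES):
            mean = np.array([3.0 * i, -3.0 * i, i, 0.5]) + scale * rng.normal(size=4) * 0.1
            A = rng.normal(size=(4, 4)) * 0.1
            out[name] = gauss(name, mean, A @ A.T + np.eye(4))
        return out

    def test_self_comparison_zero_diagonal_identity_matching(self):
        g = self._gaussians(0)
        sim = similarity_matrix(g, g)
        np.testing.assert_allclose(np.diag(sim.matrix), 0.0, atol=1e-9)
        assert sim.matching == {n: n for n in ENDOTYPE_NAMES}
        assert sim.name_match

    def test_replicates_match_on_diagonal(self):
        """Endotypes estimated from two cohorts drawn from the same published
        parameters are most similar to their namesakes."""
        gaussians = []
        for seed in (10, 20):
            out = {}
            for spec in DEVELOPMENT_SPECS:
                X = sample_endotype_points(spec, 5000, seed=seed)
                out[spec.name] = fit_endotype_gaussian(X, np.array([spec.name] * 5000), spec.name)
            gaussians.append(out)
        sim = similarity_matrix(*gaussians)
        M = sim.matrix.to_numpy()
        for i in range(4):
            off = np.concatenate([M[i, :i], M[i, i + 1 :]])
            assert M[i, i] < off.min()
        assert sim.name_match

    def test_transpose_changes_entries(self):
        a = self._gaussians(1)
        b = self._gaussians(2, scale=5.0)
        ab = similarity_matrix(a, b)
        ba = similarity_matrix(b, a)
        assert not np.allclose(ab.matrix.to_numpy(), ba.matrix.to_numpy().T)

    def test_mismatched_structure_warns(self):
        a = self._gaussians(3)
        b = dict(a)
        # swap two endotypes in b so name pairing is no longer optimal
        b["vasodilation"], b["bradycardia"] = (
            gauss("vasodilation", b["bradycardia"].mean, b["bradycardia"].cov),
            gauss("bradycardia", b["vasodilation"].mean, b["vasodilation"].cov),
        )
        with pytest.warns(UserWarning):
            sim = similarity_matrix(a, b)
        assert not sim.name_match
        assert sim.matching["vasodilation"] == "bradycardia"
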
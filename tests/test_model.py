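import numpy as np
import pytest
from scipy import stats

from dimr.errors import DataError
from dimr.model import (MixtureState, RegressionData, allocation_prior,
                        component_loglik, gene_threshold, marginal_loglik,
                        partition_log_prior, threshold)


class TestComponentLoglik:
    def test_zero_at_mode_when_variance_is_inv_2pi(self):
        # N(mu, 1/(2pi)) has density exactly 1 at its mode
        x = np.array([1.0, 2.0])
        beta = np.array([0.5, 0.25])
        y = x @ beta
        assert component_loglik(y, x, beta, 1 / (2 * np.pi)) \
            == pytest.approx(0.0, abs=1e-14)

    def test_density_integrates_to_one(self):
        x = np.array([1.0, -1.0, 2.0])
        beta = np.array([0.3, 1.1, -0.4])
        grid = np.linspace(-30, 30, 20001)
        dens = np.exp([component_loglik(y, x, beta, 2.3) for y in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_matches_normal_pdf_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=4)
            beta = rng.normal(size=4)
            y = rng.normal()
            s2 = rng.uniform(0.1, 5.0)
            expected = stats.norm.logpdf(y, loc=x @ beta, scale=np.sqrt(s2))
            assert component_loglik(y, x, beta, s2) \
                == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(DataError):
            component_loglik(0.0, np.array([1.0]), np.array([1.0]), 0.0)


class TestThreshold:
    def test_two_member_cluster_single_pair(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.8
        z = np.array([0, 0])
        assert threshold(0, z, S) == pytest.approx(0.8)

    def test_singleton_cluster_threshold_zero(self):
        S = np.ones((3, 3))
        z = np.array([0, 1, 1])
        assert threshold(0, z, S) == 0.0

    def test_linear_interpolation_quantile(self):
        # gene 0 in a 5-member cluster with co-member sims .1 .2 .3 .4
        S = np.eye(5)
        for j, s in enumerate([0.1, 0.2, 0.3, 0.4], start=1):
            S[0, j] = S[j, 0] = s
        z = np.zeros(5, dtype=int)
        assert threshold(0, z, S) == pytest.approx(0.375)

    def test_gene_threshold_excludes_self(self):
        S = np.ones((4, 4))
        assert gene_threshold(2, np.array([0, 1, 2, 3]), S) == 1.0
        assert gene_threshold(2, np.array([2]), S) == 0.0


class TestAllocationPrior:
    def test_crp_reduction_with_null_similarity(self):
        # cluster sizes {2, 3}, alpha = 1 -> probabilities 2/6, 3/6, 1/6
        z = np.array([0, 0, 1, 1, 1, 0])   # gene 5 is the one reassigned
        S = np.eye(6)
        labels, w, w_new, probs = allocation_prior(5, z, S, 1.0, 0.0)
        np.testing.assert_array_equal(labels, [0, 1])
        np.testing.assert_allclose(probs, [2 / 6, 3 / 6, 1 / 6])

    def test_hand_worked_similarity_example(self):
        # one cluster, sims to gene i (0.9, 0.8, 0.1), T_i = 0.5:
        # n* = 2, h = 1 + 1.8 = 2.8 -> weight 5.6; new slot alpha = 1
        S = np.eye(4)
        for j, s in enumerate([0.9, 0.8, 0.1]):
            S[3, j] = S[j, 3] = s
        z = np.array([0, 0, 0, 0])
        labels, w, w_new, probs = allocation_prior(3, z, S, 1.0, 0.5)
        assert w[0] == pytest.approx(2 * (1 + 1.8))
        assert probs[0] == pytest.approx(5.6 / 6.6)
        assert probs[-1] == pytest.approx(1 / 6.6)

    def test_probabilities_sum_to_one_random_states(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            z = rng.integers(0, 3, size=n)
            S = rng.uniform(size=(n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            i = int(rng.integers(n))
            T = float(rng.uniform(0, 1))
            _, _, _, probs = allocation_prior(i, z, S, 0.7, T)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (probs >= 0).all()

    def test_weight_monotone_in_similarity(self):
        # raising S_ij for j in component k (above threshold) never
        # lowers the probability of joining k
        z = np.array([0, 0, 1, 1, 2])
        base = np.eye(5) * 0 + 0.2
        np.fill_diagonal(base, 1.0)
        i = 4
        _, _, _, p0 = allocation_prior(i, z, base, 1.0, 0.0)
        boosted = base.copy()
        boosted[i, 0] = boosted[0, i] = 0.9
        _, _, _, p1 = allocation_prior(i, z, boosted, 1.0, 0.0)
        assert p1[0] > p0[0]

    def test_equal_likelihood_prefers_similar_cluster(self):
        # sim 1 to every member of cluster A, 0 to cluster B (same size)
        z = np.array([0, 0, 1, 1, 0])
        S = np.eye(5)
        S[4, :2] = S[:2, 4] = 1.0
        _, _, _, probs = allocation_prior(4, z, S, 1.0, 0.0)
        assert probs[0] > probs[1]

    def test_permutation_equivariance(self, rng):
        # permuting genes together with S leaves probabilities invariant
        n = 8
        z = rng.integers(0, 3, size=n)
        S = rng.uniform(size=(n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        perm = rng.permutation(n)
        zp = z[perm]
        Sp = S[np.ix_(perm, perm)]
        i = 3
        ip = int(np.flatnonzero(perm == i)[0])
        _, _, _, p = allocation_prior(i, z, S, 1.3, 0.2)
        _, _, _, pp = allocation_prior(ip, zp, Sp, 1.3, 0.2)
        np.testing.assert_allclose(np.sort(p), np.sort(pp), atol=1e-12)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(DataError):
            allocation_prior(0, np.array([0, 0]), np.eye(2), 0.0, 0.0)


class TestMarginalLoglik:
    def test_single_component_reduces_to_gaussian_loglik(self, rng):
        n, p = 20, 3
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(size=n)
        data = RegressionData(y, X)
        state = MixtureState(np.zeros(n, dtype=int), beta[None, :],
                             np.array([1.3]), np.array([1.0]))
        expected = stats.norm.logpdf(y, loc=X @ beta,
                                     scale=np.sqrt(1.3)).sum()
        assert marginal_loglik(data, state) == pytest.approx(expected,
                                                             abs=1e-10)

    def test_empty_component_with_zero_weight_is_ignored(self, rng):
        n, p = 10, 2
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        data = RegressionData(y, X)
        b = rng.normal(size=(1, p))
        s1 = MixtureState(np.zeros(n, dtype=int), b, np.array([1.0]),
                          np.array([1.0]))
        b2 = np.vstack([b, rng.normal(size=p)])
        s2 = MixtureState(np.zeros(n, dtype=int), b2, np.array([1.0, 1.0]),
                          np.array([1.0, 0.0]))
        assert marginal_loglik(data, s1) == pytest.approx(
            marginal_loglik(data, s2), abs=1e-12)

    def test_matches_brute_force_toy(self):
        # 5 genes, K = 2, evaluated against a direct double loop
        y = np.array([0.5, -1.0, 2.0, 0.0, 1.5])
        X = np.array([[1.0, 0.2], [1.0, -0.5], [1.0, 1.0],
                      [1.0, 0.0], [1.0, 0.8]])
        beta = np.array([[0.0, 1.0], [1.0, -1.0]])
        s2 = np.array([0.5, 2.0])
        pi = np.array([0.4, 0.6])
        expected = 0.0
        for i in range(5):
            tot = 0.0
            for k in range(2):
                mu = X[i] @ beta[k]
                tot += pi[k] * np.exp(-0.5 * (y[i] - mu) ** 2 / s2[k]) \
                    / np.sqrt(2 * np.pi * s2[k])
            expected += np.log(tot)
        data = RegressionData(y, X)
        state = MixtureState(np.array([0, 0, 1, 1, 0]), beta, s2, pi)
        assert marginal_loglik(data, state) == pytest.approx(expected,
                                                             abs=1e-12)


class TestPartitionLogPrior:
    def test_null_similarity_matches_crp_pseudo_score(self):
        # with S = I every gene's own weight is its cluster size minus 1
        # (or alpha for singletons)
        z = np.array([0, 0, 0, 1, 1, 2])
        S = np.eye(6)
        alpha = 1.0
        expected = 0.0
        for i in range(6):
            sizes = np.bincount(np.delete(z, i), minlength=z.max() + 1)
            own = sizes[z[i]] if sizes[z[i]] > 0 else alpha
            c = sizes.sum() + alpha
            expected += np.log(max(own, alpha)) - np.log(c)
        assert partition_log_prior(z, S, alpha) == pytest.approx(expected,
                                                                 abs=1e-12)


# ---------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
       st.floats(0.01, 0.99))
def test_gene_threshold_bounded_by_observed_similarities(sims, q):
    """The threshold always lies within the range of gene i's
    similarities to its co-members."""
    n = len(sims) + 1
    S = np.eye(n)
    S[0, 1:] = S[1:, 0] = sims
    t = gene_threshold(0, np.arange(n), S, q=q)
    assert min(sims) - 1e-12 <= t <= max(sims) + 1e-12
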
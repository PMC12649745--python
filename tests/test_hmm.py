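import numpy as np
import pytest
from scipy.stats import multivariate_normal

from helpers import enumerate_hmm, random_hmm_params
from statescape.hmm import (
    HMMParams,
    align_states,
    em_fit,
    forward_backward,
    viterbi,
)


def _params(pi, A, covs):
    return HMMParams(K=len(pi), pi=np.asarray(pi, float), A=np.asarray(A, float),
                     state_cov=np.asarray(covs, float))


class TestForwardBackward:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((50, 3))
        cov = np.eye(3) * 1.3
        params = _params([1.0], [[1.0]], [cov])
        gamma, xi_sum, ll = forward_backward(Y, params)
        assert np.array_equal(gamma, np.ones((50, 1)))
        assert xi_sum[0, 0] == pytest.approx(49.0, abs=1e-8)
        expect = multivariate_normal(np.zeros(3), cov).logpdf(Y).sum()
        assert ll == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("K,T,seed", [(2, 6, 0), (2, 8, 1), (3, 5, 2), (3, 6, 3)])
    def test_matches_exhaustive_enumeration(self, K, T, seed):
        """Posterior, expected transitions and log-likelihood equal the sum
        over all K^T paths."""
        rng = np.random.default_rng(seed)
        pi, A, covs = random_hmm_params(K, 2, rng)
        Y = rng.standard_normal((T, 2))
        oracle = enumerate_hmm(Y, pi, A, covs)
        gamma, xi_sum, ll = forward_backward(Y, _params(pi, A, covs))
        assert abs(ll - oracle["loglik"]) < 1e-10
        assert np.abs(gamma - oracle["gamma"]).max() < 1e-10
        assert np.abs(xi_sum - oracle["xi_sum"]).max() < 1e-10

    def test_absorbing_chain_concentrates(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((30, 2))
        params = _params([1.0, 0.0], np.eye(2), [np.eye(2), 2 * np.eye(2)])
        gamma, _, _ = forward_backward(Y, params)
        assert np.abs(gamma[:, 0] - 1.0).max() < 1e-12

    def test_posterior_consistency_long_sequence(self):
        """Rows sum to one and xi totals T-1 even at T = 10^4."""
        rng = np.random.default_rng(5)
        pi, A, covs = random_hmm_params(3, 4, rng)
        Y = rng.standard_normal((10_000, 4))
        gamma, xi_sum, ll = forward_backward(Y, _params(pi, A, covs))
        assert np.isfinite(ll)
        assert np.abs(gamma.sum(axis=1) - 1.0).max() < 1e-8
        assert xi_sum.sum() == pytest.approx(9999.0, abs=1e-6)
        assert (xi_sum >= 0).all()
        # expected departures from k cannot exceed its total occupancy
        assert (xi_sum.sum(axis=1) <= gamma.sum(axis=0) + 1e-6).all()

    def test_loglik_matches_hmmlearn(self):
        """Independent cross-check of the likelihood against hmmlearn."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(6)
        pi, A, covs = random_hmm_params(3, 3, rng)
        Y = rng.standard_normal((200, 3))
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                     init_params="")
        model.startprob_ = pi
        model.transmat_ = A
        model.means_ = np.zeros((3, 3))
        model.covars_ = covs
        _, _, ll = forward_backward(Y, _params(pi, A, covs))
        assert ll == pytest.approx(model.score(Y), abs=1e-8)


class TestViterbi:
    def test_single_state_constant(self):
        Y = np.random.default_rng(0).standard_normal((20, 2))
        path = viterbi(Y, _params([1.0], [[1.0]], [np.eye(2)]))
        assert (path == 0).all()

    @pytest.mark.parametrize("K,T,seed", [(2, 6, 10), (2, 8, 11), (3, 6, 12)])
    def test_matches_brute_force(self, K, T, seed):
        rng = np.random.default_rng(seed)
        pi, A, covs = random_hmm_params(K, 2, rng)
        Y = rng.standard_normal((T, 2))
        oracle = enumerate_hmm(Y, pi, A, covs)
        np.testing.assert_array_equal(viterbi(Y, _params(pi, A, covs)), oracle["viterbi"])


class TestEMFit:
    def test_single_state_closed_form_covariance(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((2000, 3)) @ np.diag([1.0, 2.0, 0.5])
        params, probs, diag = em_fit([Y], K=1, n_restarts=1, max_iter=5, seed=0, ridge=0.0)
        S = Y.T @ Y / len(Y)
        assert np.abs(params.state_cov[0] - S).max() < 1e-8

    def test_determinism_bit_for_bit(self):
        rng = np.random.default_rng(8)
        trials = [rng.standard_normal((150, 3)) for _ in range(4)]
        p1, _, _ = em_fit(trials, K=2, n_restarts=2, max_iter=10, seed=42)
        p2, _, _ = em_fit(trials, K=2, n_restarts=2, max_iter=10, seed=42)
        assert np.array_equal(p1.A, p2.A)
        assert np.array_equal(p1.pi, p2.pi)
        assert np.array_equal(p1.state_cov, p2.state_cov)

    def test_loglik_monotone_over_iterations(self, recovery_fit):
        hist = np.asarray(recovery_fit["diag"]["loglik_history"])
        assert (np.diff(hist) >= -1e-6 * np.abs(hist[:-1])).all()

    def test_two_state_parameter_recovery(self):
        """Well-separated covariances: recovered A within 0.05 entrywise
        after alignment (direct Gaussian data, no embedding)."""
        rng = np.random.default_rng(9)
        A = np.array([[0.95, 0.05], [0.08, 0.92]])
        covs = np.stack([np.diag([1.0, 1.0]), np.diag([16.0, 0.1])])
        from statescape.synth import simulate_markov_chain

        s = simulate_markov_chain(A, [0.5, 0.5], 100_000, seed=1)
        L = np.linalg.cholesky(covs)
        Y = np.einsum("kij,tj->tik", L, rng.standard_normal((100_000, 2)))
        Y = Y[np.arange(100_000), :, s]
        params, probs, _ = em_fit([Y], K=2, n_restarts=2, max_iter=50, seed=3)
        onehot = np.eye(2)[s]
        perm = align_states(onehot, probs.gammas[0])
        Ahat = params.A[np.ix_(perm, perm)]
        assert np.abs(Ahat - A).max() < 0.05
        agree = (np.argmax(probs.gammas[0][:, perm], axis=1) == s).mean()
        assert agree > 0.95

    def test_gamma_rows_sum_to_one(self, recovery_fit):
        G = np.vstack(recovery_fit["probs"].gammas)
        assert np.abs(G.sum(axis=1) - 1.0).max() < 1e-8
        assert (G >= 0).all() and (G <= 1).all()

    def test_xi_totals_per_trial(self, recovery_fit):
        probs = recovery_fit["probs"]
        for g, xi in zip(probs.gammas[:20], probs.xi_sums[:20]):
            assert xi.sum() == pytest.approx(len(g) - 1, abs=1e-6)


class TestAlignStates:
    def test_identity_and_swap(self):
        rng = np.random.default_rng(10)
        G = rng.dirichlet(np.ones(3), size=500)
        np.testing.assert_array_equal(align_states(G, G), [0, 1, 2])
        # candidate columns are ref columns shuffled by (2, 0, 1); aligning
        # back requires the inverse permutation
        np.testing.assert_array_equal(align_states(G, G[:, [2, 0, 1]]), [1, 2, 0])

    def test_matches_brute_force_assignment(self):
        import itertools

        rng = np.random.default_rng(11)
        R = rng.dirichlet(np.ones(3), size=200)
        C = rng.dirichlet(np.ones(3), size=200)
        perm = align_states(R, C)

        def total_corr(p):
            return sum(
                np.corrcoef(R[:, i], C[:, p[i]])[0, 1] for i in range(3)
            )

        best = max(itertools.permutations(range(3)), key=total_corr)
        assert total_corr(perm) == pytest.approx(total_corr(best), abs=1e-12)

    def test_constant_column_gets_zero_correlation(self):
        rng = np.random.default_rng(12)
        R = rng.dirichlet(np.ones(2), size=100)
        C = np.column_stack([np.full(100, 0.5), rng.random(100)])
        perm = align_states(R, C)
        assert sorted(perm.tolist()) == [0, 1]
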
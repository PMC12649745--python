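import warnings

import numpy as np
import pytest
from scipy.signal import csd as scipy_csd

from statescape import GroundTruthScene, simulate_epochs
from statescape.spectra import (
    coherence_from_csd,
    nnmf_modes,
    project_to_modes,
    state_cross_spectra,
    _mu_nnmf,
)


class TestStateCrossSpectra:
    def test_unit_gamma_reduces_to_welch(self):
        """With gamma identically 1 the weighted estimator equals plain
        Welch averaging for every channel pair."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 1200))
        g = np.ones((1200, 1))
        sp = state_cross_spectra([X], [g], [np.arange(1200)], fs=100, nperseg=64, overlap=0.5)
        for i in range(3):
            for j in range(3):
                f, Pxy = scipy_csd(X[i], X[j], fs=100, window="hann",
                                   nperseg=64, noverlap=32, detrend=False)
                np.testing.assert_allclose(sp.csd[0, :, i, j], Pxy, atol=1e-10)
        np.testing.assert_allclose(sp.freqs, f)

    def test_planted_pair_peaks_at_resonance(self):
        """A 10 Hz coupled pair puts that state's coherence peak within one
        frequency bin of 10 Hz."""
        scene = GroundTruthScene(
            n_parcels=3, fs=100.0, epoch_length_s=30.0, K_true=1,
            state_specs=[[(0, 1, 10.0, 0.9)]], noise_sd=0.8,
        )
        epochs, _ = simulate_epochs(scene, 1, participants=["p"], seed=1)
        T = epochs.trials[0].shape[1]
        g = np.ones((T, 1))
        sp = state_cross_spectra(epochs.trials, [g], [np.arange(T)], fs=100, nperseg=64)
        band = sp.coh[0, 1:, 0, 1]  # skip DC
        peak = sp.freqs[1:][np.argmax(band)]
        df = sp.freqs[1] - sp.freqs[0]
        assert abs(peak - 10.0) <= df + 1e-9

    def test_disjoint_states_recover_their_own_halves(self):
        """Two states occupying disjoint halves: each state's CSD matches
        the Welch CSD of its own half at the spectral peak within 5%."""
        rng = np.random.default_rng(2)
        from scipy.signal import lfilter

        T = 4096
        x1 = lfilter([1.0], [1.0, -1.8 * np.cos(2 * np.pi * 0.1), 0.81],
                     rng.standard_normal(T))
        x2 = rng.standard_normal(T)
        X = np.concatenate([x1, x2])[None, :]
        g = np.zeros((2 * T, 2))
        g[:T, 0] = 1.0
        g[T:, 1] = 1.0
        sp = state_cross_spectra([X], [g], [np.arange(2 * T)], fs=100, nperseg=128)
        from scipy.signal import welch

        f, P1 = welch(x1, fs=100, window="hann", nperseg=128, noverlap=64, detrend=False)
        peak = np.argmax(P1)
        assert abs(sp.csd[0, peak, 0, 0].real - P1[peak]) / P1[peak] < 0.05

    def test_all_zero_state_weight_rejected(self):
        X = np.random.default_rng(0).standard_normal((2, 300))
        g = np.zeros((300, 2))
        g[:, 0] = 1.0
        with pytest.raises(ValueError, match="all-zero"):
            state_cross_spectra([X], [g], [np.arange(300)], fs=100, nperseg=64)


class TestCoherence:
    def test_identical_channels_full_coherence(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        X = np.vstack([x, x])
        g = np.ones((2000, 1))
        sp = state_cross_spectra([X], [g], [np.arange(2000)], fs=100, nperseg=64)
        assert np.abs(sp.coh[0, :, 0, 1] - 1.0).max() < 1e-10

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((2, 200_000))
        g = np.ones((200_000, 1))
        sp = state_cross_spectra([X], [g], [np.arange(200_000)], fs=100, nperseg=64)
        assert sp.coh[0, :, 0, 1].max() < 0.05

    def test_hand_built_csd(self):
        csd = np.array([[[4.0 + 0j, 2j], [-2j, 4.0 + 0j]]])
        coh = coherence_from_csd(csd)
        assert coh[0, 0, 1] == pytest.approx(0.25)
        assert coh[0, 0, 0] == pytest.approx(1.0)

    def test_zero_power_flagged(self):
        csd = np.array([[[0.0 + 0j, 0j], [0j, 4.0 + 0j]]])
        with pytest.warns(UserWarning, match="zero diagonal"):
            coh = coherence_from_csd(csd)
        assert coh[0, 0, 1] == 0.0

    def test_bounds_on_estimates(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 1000))
        g = rng.dirichlet(np.ones(2), size=1000)
        sp = state_cross_spectra([X], [g], [np.arange(1000)], fs=50, nperseg=64)
        assert (sp.coh >= 0).all() and (sp.coh <= 1).all()
        herm = np.abs(sp.csd - np.conj(np.transpose(sp.csd, (0, 1, 3, 2)))).max()
        assert herm < 1e-12


class TestNNMF:
    def _planted_rank2(self, rng):
        f = np.linspace(1, 50, 40)
        b1 = np.exp(-0.5 * ((f - 10) / 2) ** 2) * (f < 20)
        b2 = np.exp(-0.5 * ((f - 30) / 3) ** 2) * (f >= 20)
        W = rng.random((30, 2))
        W[:5, 1] = 0.0   # some rows load purely on each mode, making the
        W[5:10, 0] = 0.0  # factorization identifiable
        return f, b1, b2, W @ np.vstack([b1, b2])

    def test_recovers_planted_rank2_factors(self):
        rng = np.random.default_rng(6)
        f, b1, b2, V = self._planted_rank2(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes, C = nnmf_modes(V, f, n_modes=2, seed=0, n_restarts=3,
                                  max_iter=50_000, tol=0.0)
        assert np.linalg.norm(V - C @ modes.weights) < 1e-6
        for planted, got in [(b1, modes.weights[0]), (b2, modes.weights[1])]:
            cos = planted @ got / np.linalg.norm(planted) / np.linalg.norm(got)
            assert cos > 0.99
        assert modes.excluded_mode_index is None

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(7)
        V = rng.random((20, 15))
        _, _, hist, _ = _mu_nnmf(V, 3, rng, max_iter=200, tol=0.0)
        assert (np.diff(hist) <= 1e-10).all()

    def test_matches_sklearn_objective(self):
        """Independent cross-check: our best factorization achieves an
        objective within 2% of scikit-learn's NMF on the same input."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(8)
        V = rng.random((25, 18))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes, C = nnmf_modes(V, np.arange(18.0), n_modes=3, seed=0, n_restarts=3)
            ours = np.linalg.norm(V - C @ modes.weights)
            sk = NMF(n_components=3, solver="mu", max_iter=2000, init="random",
                     random_state=0).fit(V)
            theirs = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert ours <= theirs * 1.02

    def test_broadband_mode_flagged(self):
        """A planted 1/f profile plus an alpha bump: the 1/f-like mode is
        excluded, the oscillatory one kept."""
        rng = np.random.default_rng(9)
        f = np.linspace(1, 40, 40)
        one_over_f = 1.0 / f
        alpha = np.exp(-0.5 * ((f - 10) / 1.5) ** 2)
        W = rng.random((40, 2)) + 0.1
        V = W @ np.vstack([one_over_f, alpha])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes, _ = nnmf_modes(V, f, n_modes=2, seed=1, n_restarts=3,
                                  max_iter=20_000, tol=1e-12)
        assert modes.excluded_mode_index is not None
        ex = modes.weights[modes.excluded_mode_index]
        cos = ex @ one_over_f / np.linalg.norm(ex) / np.linalg.norm(one_over_f)
        assert cos > 0.95

    def test_modes_sorted_by_mean_frequency_and_unit_sum(self):
        rng = np.random.default_rng(10)
        V = rng.random((30, 20))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes, _ = nnmf_modes(V, np.linspace(1, 20, 20), n_modes=3, seed=0)
        np.testing.assert_allclose(modes.weights.sum(axis=1), 1.0, atol=1e-9)
        mf = modes.weights @ modes.freqs
        assert (np.diff(mf) >= -1e-9).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nnmf_modes(-np.ones((12, 10)), np.arange(10.0), n_modes=2)


class TestProjectToModes:
    def _spectra(self, rng, F=16, P=3):
        from statescape.spectra import StateSpectra

        coh = rng.random((2, F, P, P))
        coh = 0.5 * (coh + np.transpose(coh, (0, 1, 3, 2)))
        freqs = np.linspace(0, 30, F)
        return StateSpectra(freqs=freqs, csd=coh.astype(complex), coh=coh,
                            reliable=np.ones(2, bool), total_weight=np.ones(2))

    def test_uniform_mode_is_plain_mean(self):
        from statescape.spectra import FrequencyModes

        rng = np.random.default_rng(11)
        sp = self._spectra(rng)
        modes = FrequencyModes(1, sp.freqs, np.full((1, 16), 1 / 16), ["m"], None)
        out = project_to_modes(sp, modes)
        np.testing.assert_allclose(out[:, 0], sp.coh.mean(axis=1), atol=1e-12)

    def test_delta_mode_selects_single_bin(self):
        from statescape.spectra import FrequencyModes

        rng = np.random.default_rng(12)
        sp = self._spectra(rng)
        w = np.zeros((1, 16))
        w[0, 5] = 1.0
        modes = FrequencyModes(1, sp.freqs, w, ["m"], None)
        np.testing.assert_allclose(project_to_modes(sp, modes)[:, 0], sp.coh[:, 5])

    def test_grid_mismatch_rejected(self):
        from statescape.spectra import FrequencyModes

        rng = np.random.default_rng(13)
        sp = self._spectra(rng)
        modes = FrequencyModes(1, sp.freqs[:-1], np.full((1, 15), 1 / 15), ["m"], None)
        with pytest.raises(ValueError, match="grid"):
            project_to_modes(sp, modes)
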
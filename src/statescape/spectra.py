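"""State-resolved spectra: gamma-weighted cross-spectra, coherence, NNMF modes.

The cross-spectral density of each state is estimated by Welch-style
averaging of Hann-tapered segment periodograms, with each segment weighted
by the segment-mean posterior probability (gamma) of the state. When a
state's gamma is identically one, the estimate reduces exactly to the
ordinary Welch CSD. Non-negative matrix factorization of the coherence
spectra (stacked over states and parcel pairs) yields data-driven frequency
modes; a low-frequency monotone-decreasing mode is flagged as broadband
(1/f-like) and excluded from oscillatory interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal.windows import hann
from scipy.stats import spearmanr


@dataclass
class StateSpectra:
    freqs: np.ndarray                 # (F,)
    csd: np.ndarray                   # (K, F, P, P) complex, Hermitian per frequency
    coh: np.ndarray                   # (K, F, P, P) in [0, 1]
    reliable: np.ndarray              # (K,) bool: total segment weight >= 10
    total_weight: np.ndarray          # (K,)


@dataclass
class FrequencyModes:
    n_modes: int
    freqs: np.ndarray
    weights: np.ndarray               # (n_modes, F), unit-sum rows
    mode_labels: List[str]
    excluded_mode_index: Optional[int]
    converged: bool = True


def state_cross_spectra(
    trials: Sequence[np.ndarray],
    gammas: Sequence[np.ndarray],
    sample_maps: Sequence[np.ndarray],
    fs: float,
    nperseg: int = 64,
    overlap: float = 0.5,
) -> StateSpectra:
    """Gamma-weighted Welch cross-spectral matrices per state.

    Parameters
    ----------
    trials : per-trial ``(n_parcels, n_samples)`` matrices.
    gammas : per-trial ``(valid_samples, K)`` posteriors.
    sample_maps : per-trial index arrays mapping gamma rows to original
        sample indices (the embedding's valid-row mapping); edge samples
        without gammas are excluded from spectral averaging.
    """
    nperseg = int(nperseg)
    step = max(1, int(round(nperseg * (1.0 - overlap))))
    win = hann(nperseg, sym=False)
    norm = fs * (win ** 2).sum()
    K = gammas[0].shape[1]
    P = trials[0].shape[0]
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    F = freqs.size
    acc = np.zeros((K, F, P, P), dtype=complex)
    wsum = np.zeros(K)
    nseg = np.zeros(K)
    for X, G, idx in zip(trials, gammas, sample_maps):
        seg_data = X[:, idx]                      # valid-sample range only
        Tv = seg_data.shape[1]
        for start in range(0, Tv - nperseg + 1, step):
            seg = seg_data[:, start : start + nperseg] * win
            Xf = np.fft.rfft(seg, axis=1) / np.sqrt(norm)     # (P, F)
            cross = np.einsum("if,jf->fij", np.conj(Xf), Xf)
            w = G[start : start + nperseg].mean(axis=0)       # (K,)
            acc += w[:, None, None, None] * cross[None]
            wsum += w
            nseg += w
    if (wsum == 0).any():
        bad = np.flatnonzero(wsum == 0)
        raise ValueError(f"all-zero segment weights for state(s) {bad.tolist()}")
    csd = acc / wsum[:, None, None, None]
    # one-sided scaling consistent with scipy.signal.csd(scaling='density')
    csd[:, 1:] *= 2.0
    if nperseg % 2 == 0:
        csd[:, -1] /= 2.0
    coh = coherence_from_csd(csd)
    return StateSpectra(
        freqs=freqs,
        csd=csd,
        coh=coh,
        reliable=nseg >= 10,
        total_weight=wsum,
    )


def coherence_from_csd(csd: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence from a (..., F, P, P) CSD stack.

    ``coh[f, i, j] = |csd[f, i, j]|^2 / (csd[f, i, i] * csd[f, j, j])``,
    clipped to [0, 1]; entries with zero diagonal power are set to 0 with a
    warning.
    """
    csd = np.asarray(csd)
    power = np.real(np.einsum("...ii->...i", csd))
    denom = power[..., :, None] * power[..., None, :]
    num = np.abs(csd) ** 2
    bad = denom <= 0
    if bad.any():
        warnings.warn("zero diagonal power: undefined coherence entries set to 0")
        denom = np.where(bad, 1.0, denom)
        num = np.where(bad, 0.0, num)
    return np.clip(num / denom, 0.0, 1.0)


def _mu_nnmf(
    V: np.ndarray, r: int, rng: np.random.Generator, max_iter: int, tol: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Multiplicative-update NNMF of V ~ W @ H (Frobenius objective).

    Returns (W, H, objective history, converged). The objective is
    non-increasing across updates (Lee-Seung).
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / r) if V.mean() > 0 else 1.0
    W = rng.random((n, r)) * scale + 1e-6
    H = rng.random((r, m)) * scale + 1e-6
    eps = 1e-12
    hist = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        err = np.linalg.norm(V - W @ H)
        hist.append(err)
        if prev - err < tol * max(prev, 1e-30):
            converged = True
            break
        prev = err
    return W, H, np.asarray(hist), converged


def _hals_polish(
    V: np.ndarray, W: np.ndarray, H: np.ndarray, max_iter: int, tol: float
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Hierarchical ALS sweeps to sharpen an NNMF solution.

    Coordinate-wise exact minimization per factor column; unlike the
    multiplicative rule it can reach exact zeros, so it converges fast once
    the support is nearly correct. The objective is non-increasing.
    """
    W = W.copy()
    H = H.copy()
    eps = 1e-12
    prev = np.linalg.norm(V - W @ H)
    for _ in range(max_iter):
        WtV = W.T @ V
        WtW = W.T @ W
        for j in range(H.shape[0]):
            denom = max(WtW[j, j], eps)
            H[j] = np.maximum(0.0, H[j] + (WtV[j] - WtW[j] @ H) / denom)
        VHt = V @ H.T
        HHt = H @ H.T
        for j in range(W.shape[1]):
            denom = max(HHt[j, j], eps)
            W[:, j] = np.maximum(0.0, W[:, j] + (VHt[:, j] - W @ HHt[:, j]) / denom)
        err = np.linalg.norm(V - W @ H)
        if prev - err < tol * max(prev, 1e-30):
            prev = err
            break
        prev = err
    return W, H, prev


def nnmf_modes(
    coh_stack: np.ndarray,
    freqs: np.ndarray,
    n_modes: int = 4,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> Tuple[FrequencyModes, np.ndarray]:
    """Extract non-negative frequency modes from stacked coherence spectra.

    ``coh_stack`` has one row per (state, parcel pair) and one column per
    frequency bin. Each of ``n_restarts`` runs uses multiplicative updates
    followed by HALS sweeps (both monotone in the Frobenius objective) and
    the best final fit is kept; spectral profiles are normalized to unit
    sum (scale absorbed into the coefficients) and sorted by weighted-mean
    frequency ascending.

    Broadband rule: a mode whose profile peaks in the lowest quartile of
    the grid and decreases monotonically with frequency (Spearman rho
    < -0.8) is flagged as the excluded 1/f-like mode.

    Returns the modes object and the (rows, n_modes) coefficient matrix.
    """
    V = np.asarray(coh_stack, dtype=float)
    if (V < 0).any():
        raise ValueError("coherence stack must be non-negative")
    if n_modes >= V.shape[1]:
        raise ValueError("n_modes must be smaller than the number of frequency bins")
    freqs = np.asarray(freqs, dtype=float)
    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(n_restarts):
        W, H, hist, conv = _mu_nnmf(V, n_modes, np.random.default_rng(child), max_iter, tol)
        W, H, err = _hals_polish(V, W, H, max_iter=500, tol=max(tol, 1e-14))
        if best is None or err < best[0]:
            best = (err, W, H, conv)
    err, W, H, conv = best
    if not conv:
        warnings.warn("NNMF did not converge; returning best-so-far factors")
    # unit-sum profiles, scale into coefficients
    s = H.sum(axis=1)
    s[s == 0] = 1.0
    H = H / s[:, None]
    W = W * s[None, :]
    mean_freq = H @ freqs
    order = np.argsort(mean_freq)
    H, W = H[order], W[:, order]
    excluded = None
    q1 = np.quantile(freqs, 0.25)
    for m in range(n_modes):
        peak_f = freqs[int(np.argmax(H[m]))]
        rho = spearmanr(freqs, H[m]).statistic
        # a monotone-decreasing (1/f-like) profile starts at its maximum;
        # band-limited low-frequency bumps do not and are kept
        starts_at_max = H[m, 0] >= 0.9 * H[m].max()
        if peak_f <= q1 and rho < -0.8 and starts_at_max:
            excluded = m
            break
    labels = [f"mode_{m}" for m in range(n_modes)]
    if excluded is not None:
        labels[excluded] = "broadband_1f"
    modes = FrequencyModes(
        n_modes=n_modes,
        freqs=freqs,
        weights=H,
        mode_labels=labels,
        excluded_mode_index=excluded,
        converged=bool(conv),
    )
    return modes, W


def project_to_modes(spectra: StateSpectra, modes: FrequencyModes) -> np.ndarray:
    """Mode-resolved coherence: weighted mean over frequency per mode.

    Returns a ``(K, n_modes, P, P)`` array; with unit-sum mode weights each
    slice is a weighted average of per-frequency coherence, hence symmetric
    and in [0, 1].
    """
    if modes.weights.shape[1] != spectra.freqs.size or not np.allclose(
        modes.freqs, spectra.freqs
    ):
        raise ValueError("frequency grids of spectra and modes do not match")
    return np.einsum("mf,kfij->kmij", modes.weights, spectra.coh)
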
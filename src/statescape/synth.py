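"""Ground-truth generator: Markov-switching band-limited coherent states.

The generator emulates the statistical structure the downstream analysis
assumes: a per-sample latent Markov chain switches between K states; while
state k is active, designated parcel pairs oscillate as damped AR(2)
resonators at a state-specific center frequency, driven by partially shared
innovations so that their magnitude-squared coherence at the resonance
approaches a prescribed level; all remaining parcels carry independent
noise. A two-condition experiment is realized purely as a perturbation of
the transition matrix (condition "B" uses the perturbed chain).

Coherence calibration (closed form, validated in tests): two resonators
with identical transfer function H and innovations
``e = a*z_shared + b*z_own`` (``a^2 + b^2 = 1``) have cross-spectrum
``|H|^2 a^2`` and auto-spectra ``|H|^2``, hence magnitude-squared coherence
``a^4`` at every frequency where the resonator dominates additive noise.
A target coherence ``c`` therefore uses shared amplitude ``a = c**0.25``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .containers import EpochSet, TrialMeta

# (parcel_i, parcel_j, center_freq_Hz, coupling_coherence)
PairSpec = Tuple[int, int, float, float]


@dataclass
class GroundTruthScene:
    """Full description of the synthetic generative model."""

    n_parcels: int = 10
    fs: float = 100.0
    epoch_length_s: float = 4.0
    K_true: int = 3
    A_true: np.ndarray = None
    pi_true: np.ndarray = None
    state_specs: List[List[PairSpec]] = None
    noise_sd: float = 0.3
    condition_B_delta: Dict[Tuple[int, int], float] = field(default_factory=dict)
    resonator_bandwidth_hz: float = 1.5

    def __post_init__(self):
        if self.A_true is None:
            self.A_true = _sticky_matrix(self.K_true, stay=0.98)
        self.A_true = np.asarray(self.A_true, dtype=float)
        if self.pi_true is None:
            self.pi_true = np.full(self.K_true, 1.0 / self.K_true)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        if self.state_specs is None:
            self.state_specs = [[] for _ in range(self.K_true)]
        _check_stochastic(self.A_true)
        if abs(self.pi_true.sum() - 1.0) > 1e-12 or (self.pi_true < 0).any():
            raise ValueError("pi_true is not a probability distribution")
        for k, spec in enumerate(self.state_specs):
            for (i, j, f0, c) in spec:
                if f0 >= self.fs / 2:
                    raise ValueError(
                        f"state {k}: center frequency {f0} Hz >= Nyquist {self.fs / 2} Hz"
                    )
                if not 0 <= c <= 1:
                    raise ValueError(f"state {k}: coupling coherence {c} outside [0, 1]")

    def transition_matrix(self, condition: str) -> np.ndarray:
        if condition == "B" and self.condition_B_delta:
            return perturb_transitions(self.A_true, self.condition_B_delta)
        return self.A_true


def _sticky_matrix(K: int, stay: float) -> np.ndarray:
    A = np.full((K, K), (1.0 - stay) / (K - 1) if K > 1 else 0.0)
    np.fill_diagonal(A, stay if K > 1 else 1.0)
    return A


def _check_stochastic(A: np.ndarray) -> None:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if (A < 0).any() or np.abs(A.sum(axis=1) - 1.0).max() > 1e-12:
        raise ValueError("transition matrix is not row-stochastic")


def default_scene() -> GroundTruthScene:
    """Desk-scale default scene: 10 parcels, 100 Hz, 3 spectrally distinct states.

    Each state couples two parcel pairs at its own frequency (10, 22 and
    38 Hz) with coherence 0.9; self-transition probability 0.98 gives a
    mean state lifetime of 50 samples (0.5 s). Condition B adds +0.15 to
    the 0->1 directed transition (row renormalized), the planted effect the
    condition-comparison machinery is asked to detect.
    """
    specs = [
        [(0, 1, 10.0, 0.9), (2, 3, 10.0, 0.9)],
        [(4, 5, 22.0, 0.9), (6, 7, 22.0, 0.9)],
        [(8, 9, 38.0, 0.9), (2, 4, 38.0, 0.9)],
    ]
    return GroundTruthScene(
        n_parcels=10,
        fs=100.0,
        epoch_length_s=4.0,
        K_true=3,
        state_specs=specs,
        noise_sd=0.3,
        condition_B_delta={(0, 1): 0.15},
    )


def simulate_markov_chain(A: np.ndarray, pi: np.ndarray, T: int, seed) -> np.ndarray:
    """Sample a latent state sequence: ``s[0] ~ pi``, ``s[t+1] | s[t]=k ~ A[k, :]``.

    Returns an int array of length ``T`` with values ``0..K-1``.
    """
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    _check_stochastic(A)
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(A, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(T)
    s = np.empty(T, dtype=np.int64)
    s[0] = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    row = cum[s[0]]
    for t in range(1, T):
        k = int(np.searchsorted(row, u[t], side="right"))
        s[t] = k
        row = cum[k]
    return s


def simulate_markov_chains(
    A: np.ndarray, pi: np.ndarray, T: int, n_chains: int, seed
) -> np.ndarray:
    """Sample ``n_chains`` independent state sequences at once (vectorized).

    Equivalent in law to ``n_chains`` calls of :func:`simulate_markov_chain`;
    used where many trials or replicate datasets are needed.
    Returns an ``(n_chains, T)`` int array.
    """
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    _check_stochastic(A)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(A, axis=1)
    cum[:, -1] = 1.0
    cpi = np.cumsum(pi)
    cpi[-1] = 1.0
    S = np.empty((n_chains, T), dtype=np.int64)
    u = rng.random((n_chains, T))
    S[:, 0] = np.searchsorted(cpi, u[:, 0], side="right")
    for t in range(1, T):
        S[:, t] = (u[:, t, None] >= cum[S[:, t - 1]]).sum(axis=1)
    return S


def perturb_transitions(A: np.ndarray, delta: Dict[Tuple[int, int], float]) -> np.ndarray:
    """Increment off-diagonal transition probabilities and renormalize rows.

    ``delta`` maps directed pairs ``(j, k)`` (``j != k``) to additive
    increments; each affected row is rescaled to sum to one.
    """
    A = np.array(A, dtype=float, copy=True)
    _check_stochastic(A)
    touched = set()
    for (j, k), inc in delta.items():
        if j == k:
            raise ValueError(f"delta targets must be off-diagonal, got ({j}, {k})")
        A[j, k] += inc
        if A[j, k] < 0:
            raise ValueError(f"increment drives entry ({j}, {k}) negative")
        touched.add(j)
    for j in touched:
        A[j] /= A[j].sum()
    return A


def _ar2_coeffs(f0: float, fs: float, bandwidth_hz: float) -> Tuple[float, float, float]:
    """AR(2) resonator coefficients and the innovation scale giving unit variance."""
    r = np.exp(-np.pi * bandwidth_hz / fs)
    phi1 = 2.0 * r * np.cos(2.0 * np.pi * f0 / fs)
    phi2 = -(r ** 2)
    # stationary variance of AR(2) with unit innovation variance
    var = (1 - phi2) / ((1 + phi2) * ((1 - phi2) ** 2 - phi1 ** 2))
    return phi1, phi2, 1.0 / np.sqrt(var)


def _state_generator(
    scene: GroundTruthScene, k: int, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Full-length signal of state k's generative model for all parcels.

    Coupled pairs get unit-variance resonator output with partially shared
    innovations; a parcel in several pairs receives their normalized sum;
    uncoupled parcels receive independent unit white noise.
    """
    X = np.zeros((scene.n_parcels, T))
    n_osc = np.zeros(scene.n_parcels, dtype=int)
    for (i, j, f0, c) in scene.state_specs[k]:
        phi1, phi2, e_scale = _ar2_coeffs(f0, scene.fs, scene.resonator_bandwidth_hz)
        a = c ** 0.25
        b = np.sqrt(1.0 - a * a)
        z_sh = rng.standard_normal(T)
        for p in (i, j):
            e = (a * z_sh + b * rng.standard_normal(T)) * e_scale
            X[p] += lfilter([1.0], [1.0, -phi1, -phi2], e)
            n_osc[p] += 1
    multi = n_osc > 1
    X[multi] /= np.sqrt(n_osc[multi])[:, None]
    silent = n_osc == 0
    X[silent] = rng.standard_normal((silent.sum(), T))
    return X


def simulate_epochs(
    scene: GroundTruthScene,
    n_trials_per_condition: int = 40,
    participants: int | Sequence[str] = 10,
    seed: int | np.random.Generator = 0,
) -> Tuple[EpochSet, List[np.ndarray]]:
    """Simulate a two-condition, multi-participant epoch set with known truth.

    Per participant and condition, ``n_trials_per_condition`` epochs are
    drawn. Each trial samples a latent chain from the condition's
    transition matrix and composes the observed signal by instantaneous
    switching between the K state generators, plus additive white
    measurement noise of standard deviation ``scene.noise_sd``.

    Returns the :class:`EpochSet` and the list of true state sequences
    (one int array per trial, same order as the epoch set).
    """
    if n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(participants, int):
        participants = [f"p{pi:02d}" for pi in range(participants)]
    T = int(round(scene.epoch_length_s * scene.fs))
    A_by_cond = {c: scene.transition_matrix(c) for c in ("A", "B")}
    trials, meta, truths = [], [], []
    for pid in participants:
        for cond in ("A", "B"):
            for _ in range(n_trials_per_condition):
                s = simulate_markov_chain(A_by_cond[cond], scene.pi_true, T, rng)
                gens = np.stack(
                    [_state_generator(scene, k, T, rng) for k in range(scene.K_true)]
                )  # (K, P, T)
                X = gens[s, :, np.arange(T)].T  # (P, T)
                X = X + scene.noise_sd * rng.standard_normal(X.shape)
                trials.append(X)
                meta.append(TrialMeta(pid, cond, -scene.epoch_length_s))
                truths.append(s)
    labels = [f"parcel_{p:02d}" for p in range(scene.n_parcels)]
    return EpochSet(trials, scene.fs, labels, meta), truths
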
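"""Replicate-level calibration studies of the inferential machinery.

These routines measure operating characteristics of the condition-
comparison tests on ground-truth data: type-I error of the transition
permutation test when the two conditions share one transition matrix,
its power against a planted directed-transition increase, and the
sensitivity/specificity of the mixture-model connection threshold on a
planted bimodal sample. They are used by the calibration tests and the
reproduction script; per-trial transition matrices are derived from the
true latent paths, isolating the statistical machinery from HMM
estimation error.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .dynstats import TrialDynamics, permutation_test_transitions, trial_transition_matrix
from .sigconn import gmm_threshold
from .synth import default_scene, perturb_transitions, simulate_markov_chains


def _trial_matrices_from_chains(S: np.ndarray, K: int) -> np.ndarray:
    """Per-chain empirical transition matrices (uniform rows where unvisited)."""
    n, T = S.shape
    idx = S[:, :-1] * K + S[:, 1:]
    counts = np.zeros((n, K * K))
    np.add.at(counts, (np.repeat(np.arange(n), T - 1), idx.ravel()), 1.0)
    counts = counts.reshape(n, K, K)
    out = np.empty_like(counts)
    for i in range(n):
        out[i], _ = trial_transition_matrix(counts[i])
    return out


def _make_dynamics(mats, participants, conditions) -> list:
    K = mats.shape[1]
    return [
        TrialDynamics(
            trial_id=i,
            participant_id=str(participants[i]),
            condition=str(conditions[i]),
            transition_matrix=mats[i],
            uniform_row_flags=np.zeros(K, dtype=bool),
            lifetimes_s=[np.asarray([])] * K,
            fo=np.full(K, 1.0 / K),
            switch_rate=0.0,
        )
        for i in range(mats.shape[0])
    ]


def _simulate_condition_dataset(
    A_a: np.ndarray,
    A_b: np.ndarray,
    pi: np.ndarray,
    T: int,
    n_trials: int,
    n_participants: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced two-condition dataset of per-trial transition matrices."""
    K = A_a.shape[0]
    half = n_trials // 2
    Sa = simulate_markov_chains(A_a, pi, T, half, rng)
    Sb = simulate_markov_chains(A_b, pi, T, n_trials - half, rng)
    mats = np.concatenate(
        [_trial_matrices_from_chains(Sa, K), _trial_matrices_from_chains(Sb, K)]
    )
    conditions = np.array(["A"] * half + ["B"] * (n_trials - half))
    # interleave participants so each has both conditions
    participants = np.concatenate(
        [np.arange(half) % n_participants, np.arange(n_trials - half) % n_participants]
    )
    return mats, participants, conditions


def transition_test_type1(
    n_replicates: int = 200,
    n_trials: int = 200,
    n_participants: int = 10,
    T: int = 400,
    n_perm: int = 500,
    q: float = 0.05,
    seed: int = 0,
) -> float:
    """False-rejection rate of the transition test under a shared chain.

    Both conditions use the default scene's base transition matrix
    (delta = 0), so every directed pair is a true null; the returned rate
    is total rejections over total directed-pair decisions (both
    one-sided directions) across replicates.
    """
    scene = default_scene()
    A, pi = scene.A_true, scene.pi_true
    rng = np.random.default_rng(seed)
    rejected = 0
    tested = 0
    for _ in range(n_replicates):
        mats, parts, conds = _simulate_condition_dataset(
            A, A, pi, T, n_trials, n_participants, rng
        )
        res = permutation_test_transitions(
            _make_dynamics(mats, parts, conds),
            n_perm=n_perm,
            q=q,
            seed=int(rng.integers(2**31)),
        )
        for lv in res.condition_levels:
            rejected += int(res.rejected[lv].sum())
            tested += len(res.pairs)
    return rejected / tested


def transition_test_power(
    delta: float = 0.15,
    pair: Tuple[int, int] = (0, 1),
    n_replicates: int = 100,
    n_trials: int = 800,
    n_participants: int = 10,
    T: int = 400,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the planted directed pair is detected.

    Condition B's chain adds ``delta`` to one directed transition of the
    default scene's matrix (row renormalized); detection means the pair is
    FDR-rejected in the 'increased in B' direction.
    """
    scene = default_scene()
    A, pi = scene.A_true, scene.pi_true
    A_b = perturb_transitions(A, {pair: delta})
    rng = np.random.default_rng(seed)
    hits = 0
    pair_idx = None
    for _ in range(n_replicates):
        mats, parts, conds = _simulate_condition_dataset(
            A, A_b, pi, T, n_trials, n_participants, rng
        )
        res = permutation_test_transitions(
            _make_dynamics(mats, parts, conds),
            n_perm=n_perm,
            q=q,
            seed=int(rng.integers(2**31)),
        )
        if pair_idx is None:
            pair_idx = res.pairs.index(pair)
        if res.rejected["B"][pair_idx]:
            hits += 1
    return hits / n_replicates


def gmm_planted_performance(
    n_replicates: int = 20,
    n_noise: int = 450,
    n_signal: int = 50,
    signal_mean: float = 6.0,
    alpha: float = 0.001,
    seed: int = 0,
) -> Dict[str, float]:
    """Sensitivity and false positives of the connection threshold on a
    planted N(0,1) + N(signal_mean,1) sample, averaged over replicates."""
    rng = np.random.default_rng(seed)
    flagged, fps = [], []
    for _ in range(n_replicates):
        x = np.concatenate(
            [rng.standard_normal(n_noise), signal_mean + rng.standard_normal(n_signal)]
        )
        res = gmm_threshold(x, alpha=alpha)
        flagged.append(res.mask[n_noise:].sum())
        fps.append(res.mask[:n_noise].sum())
    return {
        "mean_signal_flagged": float(np.mean(flagged)),
        "signal_sensitivity": float(np.mean(flagged) / n_signal),
        "mean_false_positives": float(np.mean(fps)),
    }


def gmm_null_false_positive_rate(
    n_replicates: int = 200, n_values: int = 500, alpha: float = 0.001, seed: int = 0
) -> float:
    """Mean false-positive count per run on pure standard-normal input."""
    rng = np.random.default_rng(seed)
    fps = [
        gmm_threshold(rng.standard_normal(n_values), alpha=alpha).mask.sum()
        for _ in range(n_replicates)
    ]
    return float(np.mean(fps))
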
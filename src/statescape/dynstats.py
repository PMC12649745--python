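"""Per-trial state dynamics and their two-condition comparison.

For every trial the pipeline derives a transition matrix (row-normalized
expected transition counts under the group model), per-state lifetimes and
switch rate (from the Viterbi path), and fractional occupancy (from the
soft posteriors). Condition differences in transition probabilities are
tested with a label permutation scheme restricted within participant
(5,000 permutations by default), one-sided per direction, with
Benjamini-Hochberg FDR over directed pairs; lifetime and FO differences
use a two-way repeated-measures ANOVA (state x condition) with post-hoc
paired permutation tests, and switch rate a one-way paired comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class TrialDynamics:
    trial_id: int
    participant_id: str
    condition: str
    transition_matrix: np.ndarray          # (K, K) row-stochastic
    uniform_row_flags: np.ndarray          # (K,) rows that had zero counts
    lifetimes_s: List[np.ndarray]          # per state, visit durations (s)
    fo: np.ndarray                         # (K,), sums to 1
    switch_rate: float                     # visits per second


@dataclass
class TransitionTestResult:
    pairs: List[Tuple[int, int]]           # directed off-diagonal pairs (j, k)
    obs_diff: np.ndarray                   # mean(cond_hi) - mean(cond_lo) per pair
    pvals: Dict[str, np.ndarray]           # per condition label: one-sided p per pair
    rejected: Dict[str, np.ndarray]        # per condition label: BH-FDR mask
    n_permutations: int
    q: float
    seed: Optional[int]
    condition_levels: Tuple[str, str] = ("A", "B")
    excluded_participants: List[str] = field(default_factory=list)


def trial_transition_matrix(xi_sum: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-normalize expected transition counts into a per-trial matrix.

    Rows with zero total count (the trial never left — or never entered —
    that state) are replaced by a uniform row and flagged.
    """
    xi = np.asarray(xi_sum, dtype=float)
    if (xi < 0).any():
        raise ValueError("expected transition counts must be non-negative")
    rs = xi.sum(axis=1)
    if rs.sum() == 0:
        raise ValueError("all-zero transition counts")
    K = xi.shape[0]
    flags = rs == 0
    T = np.where(flags[:, None], 1.0 / K, xi / np.where(rs == 0, 1.0, rs)[:, None])
    return T, flags


def lifetimes(path: np.ndarray, fs: float) -> List[np.ndarray]:
    """Per-state visit durations (seconds) by run-length encoding the path.

    First and last runs are included. States are 0-indexed; the return
    value has one array per state ``0..max_state``.
    """
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty state path")
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    K = int(path.max()) + 1
    out = [[] for _ in range(K)]
    for s, e in zip(starts, ends):
        out[int(path[s])].append((e - s) / fs)
    return [np.asarray(v) for v in out]


def fractional_occupancy(gamma: np.ndarray) -> np.ndarray:
    """Column means of the posterior: the average share of time per state."""
    gamma = np.asarray(gamma, dtype=float)
    return gamma.mean(axis=0)


def switch_rate(path: np.ndarray, fs: float) -> float:
    """State visits per second: boundary count over trial duration."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty state path")
    n_switches = int((np.diff(path) != 0).sum())
    return n_switches / (path.size / fs)


def trial_dynamics(
    xi_sums: Sequence[np.ndarray],
    gammas: Sequence[np.ndarray],
    paths: Sequence[np.ndarray],
    fs: float,
    participant_ids: Sequence[str],
    conditions: Sequence[str],
    K: int,
) -> List[TrialDynamics]:
    """Assemble per-trial dynamic statistics from HMM outputs."""
    out = []
    for i, (xi, g, p) in enumerate(zip(xi_sums, gammas, paths)):
        Tmat, flags = trial_transition_matrix(xi)
        lt = lifetimes(p, fs)
        lt += [np.asarray([])] * (K - len(lt))
        out.append(
            TrialDynamics(
                trial_id=i,
                participant_id=participant_ids[i],
                condition=conditions[i],
                transition_matrix=Tmat,
                uniform_row_flags=flags,
                lifetimes_s=lt,
                fo=fractional_occupancy(g),
                switch_rate=switch_rate(p, fs),
            )
        )
    return out


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.max(np.flatnonzero(below)))
        mask[order[: kmax + 1]] = True
    return mask


def _within_participant_label_perms(
    participants: np.ndarray,
    labels01: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_perm, n_trials) boolean matrix of permuted 'condition 1' indicators,
    shuffling labels independently within each participant."""
    n = labels01.size
    out = np.empty((n_perm, n), dtype=bool)
    groups = [np.flatnonzero(participants == p) for p in np.unique(participants)]
    for b in range(n_perm):
        lab = np.empty(n, dtype=bool)
        for idx in groups:
            lab[idx] = labels01[idx][rng.permutation(idx.size)]
        out[b] = lab
    return out


def permutation_test_transitions(
    dynamics: Sequence[TrialDynamics],
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int = 0,
) -> TransitionTestResult:
    """Directed-pair permutation test of condition differences in transition
    probability.

    The statistic for pair (j, k) is the difference of condition means of
    per-trial transition probabilities. The null permutes condition labels
    within participant (preserving each participant's condition counts);
    one-sided p-values are computed per direction with the add-one
    correction ``p = (1 + #{null >= obs}) / (n_perm + 1)`` and BH-FDR is
    applied across directed pairs separately per direction. Participants
    represented in only one condition are excluded with a warning.
    """
    conds = np.array([d.condition for d in dynamics])
    parts = np.array([d.participant_id for d in dynamics])
    levels = sorted(set(conds))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    keep = np.ones(len(dynamics), dtype=bool)
    excluded = []
    for p in np.unique(parts):
        sel = parts == p
        if len(set(conds[sel])) < 2:
            keep[sel] = False
            excluded.append(str(p))
    if excluded:
        warnings.warn(
            f"participants with a single condition excluded from permutation: {excluded}"
        )
    K = dynamics[0].transition_matrix.shape[0]
    pairs = [(j, k) for j in range(K) for k in range(K) if j != k]
    if not pairs or keep.sum() == 0:
        empty = np.zeros(len(pairs))
        return TransitionTestResult(
            pairs=pairs,
            obs_diff=empty,
            pvals={lv: np.ones(len(pairs)) for lv in levels},
            rejected={lv: np.zeros(len(pairs), dtype=bool) for lv in levels},
            n_permutations=n_perm,
            q=q,
            seed=seed,
            condition_levels=tuple(levels),
        )
    X = np.stack([d.transition_matrix for d in dynamics])[keep]    # (n, K, K)
    X = X[:, [p[0] for p in pairs], [p[1] for p in pairs]]          # (n, n_pairs)
    conds, parts = conds[keep], parts[keep]
    lab1 = conds == levels[1]
    n1, n0 = int(lab1.sum()), int((~lab1).sum())
    obs = X[lab1].mean(axis=0) - X[~lab1].mean(axis=0)              # level1 - level0
    rng = np.random.default_rng(seed)
    perm_lab = _within_participant_label_perms(parts, lab1, n_perm, rng)
    Wmat = perm_lab / n1 - (~perm_lab) / n0                         # (n_perm, n)
    null = Wmat @ X                                                 # (n_perm, n_pairs)
    # one-sided per direction, add-one corrected
    p_hi = (1 + (null >= obs).sum(axis=0)) / (n_perm + 1)           # level1 increased
    p_lo = (1 + (null <= obs).sum(axis=0)) / (n_perm + 1)           # level0 increased
    pvals = {levels[1]: p_hi, levels[0]: p_lo}
    rejected = {lv: bh_fdr(pvals[lv], q) for lv in levels}
    return TransitionTestResult(
        pairs=pairs,
        obs_diff=obs,
        pvals=pvals,
        rejected=rejected,
        n_permutations=n_perm,
        q=q,
        seed=seed,
        condition_levels=tuple(levels),
        excluded_participants=excluded,
    )


def _paired_permutation_p(diffs: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided sign-flip permutation p for paired participant differences."""
    obs = abs(diffs.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = np.abs((signs * diffs).mean(axis=1))
    return float((1 + (null >= obs - 1e-15).sum()) / (n_perm + 1))


def temporal_metric_comparison(
    cell_means: pd.DataFrame,
    metric: str,
    n_perm: int = 5000,
    q: float = 0.05,
    seed: int = 0,
) -> Dict[str, pd.DataFrame]:
    """State-by-condition comparison of a temporal metric.

    ``cell_means`` must hold one row per (participant, condition, state)
    with columns ``participant``, ``condition``, ``state``, ``value``
    (participant-level cell means). Lifetime and FO use a two-way
    repeated-measures ANOVA (factors state and condition, both within
    participant) followed by per-state paired sign-flip permutation tests
    with BH-FDR; switch rate (or a single-state design) collapses to the
    paired comparison alone.
    """
    from statsmodels.stats.anova import AnovaRM

    df = cell_means.copy()
    participants = df["participant"].unique()
    if len(participants) < 3:
        raise ValueError("need at least 3 participants for the repeated-measures comparison")
    states = sorted(df["state"].unique())
    rng = np.random.default_rng(seed)
    out: Dict[str, pd.DataFrame] = {}
    if metric != "switch_rate" and len(states) > 1:
        res = AnovaRM(
            df, depvar="value", subject="participant", within=["state", "condition"],
            aggregate_func="mean",
        ).fit()
        out["anova"] = res.anova_table.reset_index(names="effect")
    # post-hoc: per state, paired condition difference across participants
    rows = []
    levels = sorted(df["condition"].unique())
    for s in states:
        sub = df[df["state"] == s].pivot_table(
            index="participant", columns="condition", values="value"
        )
        sub = sub.dropna()
        diffs = (sub[levels[1]] - sub[levels[0]]).to_numpy()
        p = _paired_permutation_p(diffs, n_perm, rng)
        rows.append({"state": s, "mean_diff": diffs.mean(), "p": p})
    post = pd.DataFrame(rows)
    post["significant"] = bh_fdr(post["p"].to_numpy(), q)
    out["posthoc"] = post
    return out
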
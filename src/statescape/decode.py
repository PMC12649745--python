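"""Condition decoding from binned state-probability time courses.

The posterior state probabilities over the final prestimulus window
(600 ms by default) are averaged in 60 ms bins and fed to an
L1-regularized logistic regression with participant-grouped
cross-validation (no participant is split across train and test).
A cluster-based permutation test assesses whether any contiguous run of
time bins carries decodable information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression


@dataclass
class DecodingResult:
    bin_edges_s: np.ndarray
    features: np.ndarray                 # (n_trials, n_bins * K), bin-major
    fold_accuracy: np.ndarray
    mean_accuracy: float
    lambda_grid: np.ndarray              # inverse-strength grid (sklearn C)
    selected_lambda: np.ndarray          # per outer fold
    coef_mean: np.ndarray
    seed: Optional[int] = None


def bin_gammas(
    gammas: Sequence[np.ndarray],
    fs: float,
    window_ms: float = 600.0,
    bin_ms: float = 60.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Average posteriors in consecutive bins over the final window.

    Features are ordered bin-major, state-minor; a trailing partial bin is
    dropped with a warning. Returns ``(features, bin_edges_s)`` with edges
    relative to the epoch end (the stimulus side of the window).
    """
    n_bin_samples = int(round(bin_ms / 1000.0 * fs))
    if n_bin_samples < 1:
        raise ValueError("bin shorter than one sample")
    n_bins = int(np.floor(window_ms / bin_ms))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    if abs(window_ms - n_bins * bin_ms) > 1e-9:
        warnings.warn("window not divisible into bins: trailing partial bin dropped")
    n_win = n_bins * n_bin_samples
    K = gammas[0].shape[1]
    feats = np.empty((len(gammas), n_bins * K))
    for i, g in enumerate(gammas):
        if g.shape[0] < n_win:
            raise ValueError(
                f"trial {i}: window of {n_win} samples exceeds available {g.shape[0]}"
            )
        tail = g[-n_win:]
        binned = tail.reshape(n_bins, n_bin_samples, K).mean(axis=1)
        feats[i] = binned.reshape(-1)
    edges = -(window_ms / 1000.0) + np.arange(n_bins + 1) * (n_bin_samples / fs)
    return feats, edges


def _group_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Split unique groups into folds (shuffled), returning test masks."""
    uniq = np.array(sorted(set(groups)))
    order = rng.permutation(len(uniq))
    chunks = np.array_split(uniq[order], n_folds)
    return [np.isin(groups, c) for c in chunks]


def _fit_predict(Xtr, ytr, Xte, C) -> np.ndarray:
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C, max_iter=5000)
    clf.fit(Xtr, ytr)
    return clf.predict(Xte), clf.coef_.ravel()


def lasso_logistic_cv(
    features: np.ndarray,
    labels: np.ndarray,
    participant_ids: np.ndarray,
    lambda_grid: Optional[np.ndarray] = None,
    n_folds: int = 5,
    seed: int = 0,
    bin_edges_s: Optional[np.ndarray] = None,
) -> DecodingResult:
    """Participant-grouped cross-validated L1 logistic regression.

    The regularization strength is chosen per outer fold by inner
    grouped cross-validation on the training participants; reported
    accuracy is out-of-fold only. A fold containing a single class
    triggers one re-draw of the folds, then an error.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    groups = np.asarray(participant_ids)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    ybin = (y == classes[1]).astype(int)
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 2, 7)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, len(set(groups)))

    for attempt in range(2):
        folds = _group_folds(groups, n_folds, rng)
        ok = all(len(np.unique(ybin[~m])) == 2 and m.any() for m in folds)
        if ok:
            break
        if attempt == 1:
            raise ValueError("single-class fold persisted after one re-draw")

    fold_acc, sel_C, coefs = [], [], []
    for test_mask in folds:
        tr = ~test_mask
        inner_groups = groups[tr]
        inner_n = min(3, len(set(inner_groups)))
        inner_folds = _group_folds(inner_groups, inner_n, rng)
        scores = np.zeros(lambda_grid.size)
        for im in inner_folds:
            if len(np.unique(ybin[tr][~im])) < 2 or not im.any():
                continue
            for ci, C in enumerate(lambda_grid):
                pred, _ = _fit_predict(X[tr][~im], ybin[tr][~im], X[tr][im], C)
                scores[ci] += (pred == ybin[tr][im]).mean()
        best_C = lambda_grid[int(np.argmax(scores))]
        pred, coef = _fit_predict(X[tr], ybin[tr], X[test_mask], best_C)
        fold_acc.append((pred == ybin[test_mask]).mean())
        sel_C.append(best_C)
        coefs.append(coef)
    fold_acc = np.asarray(fold_acc)
    return DecodingResult(
        bin_edges_s=bin_edges_s if bin_edges_s is not None else np.array([]),
        features=X,
        fold_accuracy=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        lambda_grid=lambda_grid,
        selected_lambda=np.asarray(sel_C),
        coef_mean=np.mean(coefs, axis=0),
        seed=seed,
    )


def _per_bin_stats(
    X: np.ndarray, ybin: np.ndarray, folds: List[np.ndarray], n_bins: int, K: int, C: float
) -> np.ndarray:
    """Out-of-fold decodability (accuracy - 0.5) of each bin's K features."""
    stats = np.empty(n_bins)
    for b in range(n_bins):
        cols = slice(b * K, (b + 1) * K)
        correct = 0
        total = 0
        for m in folds:
            pred, _ = _fit_predict(X[~m][:, cols], ybin[~m], X[m][:, cols], C)
            correct += int((pred == ybin[m]).sum())
            total += int(m.sum())
        stats[b] = correct / total - 0.5
    return stats


def cluster_permutation_significance(
    features: np.ndarray,
    labels: np.ndarray,
    participant_ids: np.ndarray,
    n_bins: int,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 5,
    C: float = 1.0,
    primary_alpha: float = 0.05,
) -> Dict:
    """Cluster-corrected significance of time-resolved decodability.

    Per-bin statistic: out-of-fold accuracy of that bin's K features minus
    chance. The primary threshold for each bin is the (1 - primary_alpha)
    quantile of its permutation-null statistics (labels permuted within
    participant); clusters are maximal runs of supra-threshold bins, scored
    by summed statistic and compared against the null distribution of the
    maximum cluster mass.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null tail; refusing")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    groups = np.asarray(participant_ids)
    classes = np.unique(y)
    ybin = (y == classes[1]).astype(int)
    K = X.shape[1] // n_bins
    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, len(set(groups)))
    folds = _group_folds(groups, n_folds, rng)
    obs = _per_bin_stats(X, ybin, folds, n_bins, K, C)
    null = np.empty((n_perm, n_bins))
    uniq = np.unique(groups)
    gidx = [np.flatnonzero(groups == g) for g in uniq]
    for b in range(n_perm):
        yp = ybin.copy()
        for idx in gidx:
            yp[idx] = ybin[idx][rng.permutation(idx.size)]
        null[b] = _per_bin_stats(X, yp, folds, n_bins, K, C)
    thresh = np.quantile(null, 1.0 - primary_alpha, axis=0)
    obs_clusters = _clusters(obs > thresh, obs)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        cl = _clusters(null[b] > thresh, null[b])
        null_max[b] = max((m for _, m in cl), default=0.0)
    results = [
        {
            "bins": list(rng_),
            "mass": mass,
            "p_corrected": float((1 + (null_max >= mass).sum()) / (n_perm + 1)),
        }
        for rng_, mass in obs_clusters
    ]
    return {
        "per_bin_stat": obs,
        "threshold": thresh,
        "clusters": results,
        "n_permutations": n_perm,
        "seed": seed,
    }


def _clusters(mask: np.ndarray, stat: np.ndarray) -> List[Tuple[range, float]]:
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        if (not m or i == len(mask) - 1) and start is not None:
            end = i + 1 if (m and i == len(mask) - 1) else i
            out.append((range(start, end), float(stat[start:end].sum())))
            start = None
    return out
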
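"""Zero-mean Gaussian hidden Markov model in embedded-PCA space.

States are defined purely by their observation covariance (the data are
standardized, so lagged covariance — i.e. spectral content — is the only
thing that distinguishes them). Fitting is maximum-likelihood EM
(Baum-Welch) with exact scaled forward-backward inference; trials are
independent chains sharing {pi, A, covariances}, with no transitions
bridging trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """Model parameters: initial distribution, per-sample transition matrix,
    and one full covariance per state (means fixed at zero)."""

    K: int
    pi: np.ndarray
    A: np.ndarray
    state_cov: np.ndarray  # (K, d, d)

    def validate(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-10 or (self.pi < 0).any():
            raise ValueError("pi is not a probability distribution")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > 1e-10 or (self.A < 0).any():
            raise ValueError("A is not row-stochastic")
        for k in range(self.K):
            ev = np.linalg.eigvalsh(self.state_cov[k])
            if ev.min() <= 0:
                raise ValueError(f"state {k}: covariance is not positive definite")


@dataclass
class StateProbs:
    """Per-trial posteriors: gammas, expected transition counts, log-likelihoods."""

    gammas: List[np.ndarray]         # each (T_i, K)
    xi_sums: List[np.ndarray]        # each (K, K)
    logliks: np.ndarray              # (n_trials,)

    @property
    def K(self) -> int:
        return self.gammas[0].shape[1]

    def concatenated(self) -> np.ndarray:
        return np.vstack(self.gammas)


def _log_obs(Y: np.ndarray, params: HMMParams) -> np.ndarray:
    """Log N(y_t; 0, Sigma_k) for all samples and states -> (T, K)."""
    T, d = Y.shape
    out = np.empty((T, params.K))
    for k in range(params.K):
        try:
            L = cholesky(params.state_cov[k], lower=True)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"state {k}: singular covariance") from e
        logdet = 2.0 * np.log(np.diag(L)).sum()
        W = solve_triangular(L, Y.T, lower=True)
        out[:, k] = -0.5 * (d * _LOG2PI + logdet + (W * W).sum(axis=0))
    return out


def _forward_backward_batch(
    logB: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length chains.

    Parameters
    ----------
    logB : (n, T, K) log observation densities.

    Returns (gamma (n,T,K), xi_sum (n,K,K), loglik (n,)).
    """
    n, T, K = logB.shape
    shift = logB.max(axis=2)                     # (n, T)
    B = np.exp(logB - shift[:, :, None])
    alpha = np.empty((n, T, K))
    c = np.empty((n, T))
    a = pi[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=1)

    beta = np.empty((n, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((n, K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]   # (n, K)
        beta[:, t] = bb @ A.T
        xi_sum += alpha[:, t, :, None] * A[None, :, :] * bb[:, None, :]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma, xi_sum, loglik


def forward_backward(
    Y: np.ndarray, params: HMMParams
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Exact posteriors for one chain: (gamma, xi_sum, loglik)."""
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise ValueError("Y contains non-finite values")
    logB = _log_obs(Y, params)[None]
    gamma, xi_sum, ll = _forward_backward_batch(logB, params.A, params.pi)
    return gamma[0], xi_sum[0], float(ll[0])


def viterbi(Y: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable state path (log-space; ties break toward the lower index)."""
    Y = np.asarray(Y, dtype=float)
    logB = _log_obs(Y, params)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logA            # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _init_params(
    Y_all: np.ndarray, K: int, ridge: float, rng: np.random.Generator
) -> HMMParams:
    """Random restart initialization: each state's covariance comes from a
    random contiguous chunk of the pooled data (plus ridge), giving
    spectrally diverse starting states; A starts sticky, pi uniform."""
    N, d = Y_all.shape
    chunk = min(max(5 * d, 100), N)
    covs = np.empty((K, d, d))
    for k in range(K):
        start = int(rng.integers(0, N - chunk + 1))
        seg = Y_all[start : start + chunk]
        S = seg.T @ seg / chunk
        covs[k] = S + ridge * np.trace(S) / d * np.eye(d)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return HMMParams(K=K, pi=pi, A=A, state_cov=covs)


def _e_step(
    Y_trials: List[np.ndarray], params: HMMParams
) -> Tuple[List[np.ndarray], List[np.ndarray], np.ndarray]:
    """Batched E-step over trials grouped by length."""
    n = len(Y_trials)
    lengths = np.array([len(Y) for Y in Y_trials])
    gammas: List[np.ndarray] = [None] * n
    xi_sums: List[np.ndarray] = [None] * n
    lls = np.empty(n)
    for T in np.unique(lengths):
        idx = np.flatnonzero(lengths == T)
        logB = np.stack([_log_obs(Y_trials[i], params) for i in idx])
        g, x, ll = _forward_backward_batch(logB, params.A, params.pi)
        for pos, i in enumerate(idx):
            gammas[i] = g[pos]
            xi_sums[i] = x[pos]
            lls[i] = ll[pos]
    return gammas, xi_sums, lls


def em_fit(
    Y_trials: Sequence[np.ndarray],
    K: int,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
    ridge: float = 1e-6,
) -> Tuple[HMMParams, StateProbs, Dict]:
    """Baum-Welch fit of the zero-mean Gaussian HMM across all trials.

    The M-step is ``Sigma_k = sum_t gamma_tk y_t y_t' / sum_t gamma_tk``
    plus a ridge floor of ``ridge`` times the mean diagonal; ``A`` is the
    row-normalized pooled expected transition count; ``pi`` the normalized
    mean first-sample posterior. The best of ``n_restarts`` runs (by final
    log-likelihood) is returned. The log-likelihood is non-decreasing over
    iterations up to numerical slack.
    """
    Y_trials = [np.asarray(Y, dtype=float) for Y in Y_trials]
    if K < 1:
        raise ValueError("K must be >= 1")
    Y_all = np.vstack(Y_trials)
    N, d = Y_all.shape
    if N < K * d:
        raise ValueError("too few pooled samples for the requested model size")
    root = np.random.SeedSequence(seed)
    best = None
    diag = {"restart_logliks": [], "n_iter": [], "converged": []}
    for r, child in enumerate(root.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        params = _init_params(Y_all, K, ridge, rng)
        ll_hist = []
        reinit_used = np.zeros(K, dtype=bool)
        for it in range(max_iter):
            gammas, xi_sums, lls = _e_step(Y_trials, params)
            ll = float(lls.sum())
            ll_hist.append(ll)
            G = np.vstack(gammas)
            occ = G.sum(axis=0)
            empty = np.flatnonzero(occ < K)
            if empty.size:
                for k in empty:
                    if reinit_used[k]:
                        raise RuntimeError(
                            f"state {k} emptied twice during EM (occupancy {occ[k]:.2f})"
                        )
                    reinit_used[k] = True
                    params = _reinit_state(params, k, Y_all, ridge, rng)
                continue
            # M-step
            covs = np.empty_like(params.state_cov)
            for k in range(K):
                S = (Y_all * G[:, k : k + 1]).T @ Y_all / occ[k]
                covs[k] = S + ridge * np.trace(S) / d * np.eye(d)
                covs[k] = 0.5 * (covs[k] + covs[k].T)
            if K > 1:
                Asum = np.sum(xi_sums, axis=0)
                A = Asum / Asum.sum(axis=1, keepdims=True)
                pi = np.mean([g[0] for g in gammas], axis=0)
                pi = pi / pi.sum()
            else:
                A = np.ones((1, 1))
                pi = np.ones(1)
            params = HMMParams(K=K, pi=pi, A=A, state_cov=covs)
            if len(ll_hist) > 1:
                prev = ll_hist[-2]
                if abs(ll - prev) < tol * abs(prev):
                    break
        # final E-step under the last parameters
        gammas, xi_sums, lls = _e_step(Y_trials, params)
        ll = float(lls.sum())
        diag["restart_logliks"].append(ll)
        diag["n_iter"].append(len(ll_hist))
        diag["converged"].append(len(ll_hist) < max_iter)
        if best is None or ll > best[0]:
            best = (ll, params, StateProbs(gammas, xi_sums, lls), ll_hist)
    ll, params, probs, ll_hist = best
    diag["loglik"] = ll
    diag["loglik_history"] = ll_hist
    return params, probs, diag


def _reinit_state(
    params: HMMParams, k: int, Y_all: np.ndarray, ridge: float, rng: np.random.Generator
) -> HMMParams:
    N, d = Y_all.shape
    chunk = min(max(5 * d, 100), N)
    start = int(rng.integers(0, N - chunk + 1))
    seg = Y_all[start : start + chunk]
    S = seg.T @ seg / chunk
    covs = params.state_cov.copy()
    covs[k] = S + ridge * np.trace(S) / d * np.eye(d)
    return HMMParams(K=params.K, pi=params.pi, A=params.A, state_cov=covs)


def align_states(
    reference: np.ndarray | Sequence[np.ndarray],
    candidate: np.ndarray | Sequence[np.ndarray],
) -> np.ndarray:
    """Permutation matching candidate state columns to reference columns.

    State labels are arbitrary across runs; the returned ``perm`` maximizes
    the total Pearson correlation between matched gamma columns (solved as
    an optimal assignment), so ``candidate[:, perm]`` aligns with the
    reference. Constant columns get correlation 0 against everything.
    """
    R = np.vstack(reference) if not isinstance(reference, np.ndarray) else reference
    C = np.vstack(candidate) if not isinstance(candidate, np.ndarray) else candidate
    if R.shape != C.shape:
        raise ValueError("reference and candidate must have identical shapes")
    K = R.shape[1]
    corr = np.zeros((K, K))
    Rc = R - R.mean(axis=0)
    Cc = C - C.mean(axis=0)
    rs = np.sqrt((Rc ** 2).sum(axis=0))
    cs = np.sqrt((Cc ** 2).sum(axis=0))
    for i in range(K):
        for j in range(K):
            if rs[i] == 0 or cs[j] == 0:
                continue
            corr[i, j] = (Rc[:, i] @ Cc[:, j]) / (rs[i] * cs[j])
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=np.int64)
    perm[rows] = cols
    return perm
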
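"""Independent oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration, explicit
loops, closed forms — and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
from typing import Tuple

import numpy as np
from scipy.stats import multivariate_normal


def enumerate_hmm(Y: np.ndarray, pi, A, covs) -> dict:
    """Exact HMM quantities by summing over all K^T state paths."""
    T = len(Y)
    K = len(pi)
    d = Y.shape[1]
    obs = np.empty((T, K))
    for k in range(K):
        obs[:, k] = multivariate_normal(mean=np.zeros(d), cov=covs[k]).pdf(Y)
    total = 0.0
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    best_p, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * obs[0, path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * obs[t, path[t]]
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
        for t in range(T - 1):
            xi[path[t], path[t + 1]] += p
        if p > best_p:
            best_p, best_path = p, path
    return {
        "loglik": np.log(total),
        "gamma": gamma / total,
        "xi_sum": xi / total,
        "viterbi": np.asarray(best_path),
    }


def brute_force_bh(pvals: np.ndarray, q: float) -> np.ndarray:
    """BH step-up by explicitly trying every candidate threshold."""
    p = np.asarray(pvals)
    m = p.size
    best_thresh = 0.0
    for i in range(1, m + 1):
        t = np.sort(p)[i - 1]
        if t <= q * i / m and (p <= t).sum() >= i:
            best_thresh = max(best_thresh, t)
    # the rejected set is every p below the largest admissible sorted threshold
    kstar = 0
    ps = np.sort(p)
    for i in range(1, m + 1):
        if ps[i - 1] <= q * i / m:
            kstar = i
    if kstar == 0:
        return np.zeros(m, dtype=bool)
    return p <= ps[kstar - 1]


def random_hmm_params(K: int, d: int, rng: np.random.Generator):
    """A random valid parameter set (well-conditioned covariances)."""
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    covs = np.empty((K, d, d))
    for k in range(K):
        M = rng.standard_normal((d, d + 2))
        covs[k] = M @ M.T / (d + 2) + 0.5 * np.eye(d)
    return pi, A, covs
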
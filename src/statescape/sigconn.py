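"""Robust-connection detection via a two-component Gaussian mixture.

Mode-resolved coherence values are first demeaned across states (each
connection's mean over all states is subtracted within a frequency mode),
then, per state and mode, a one-dimensional mixture of two unit-variance
Gaussians separates background from genuinely coherent connections: the
lower-mean component models noise, and each connection's p-value is its
upper-tail probability under that noise component, Bonferroni-corrected
within the (state, mode) family at alpha = 0.001 by default.

Standardization: values are scaled by a robust noise-scale estimate
(median absolute deviation / 0.6745) so the noise component really has
approximately unit variance; a total-variance scaling would shrink the
signal component into the noise tail whenever signal connections are
plentiful or strong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm


@dataclass
class ConnectionTest:
    values: np.ndarray            # original (demeaned) values
    standardized: np.ndarray
    means: np.ndarray             # (noise_mean, signal_mean) on the standardized scale
    mixture_weights: np.ndarray
    pvals: np.ndarray
    mask: np.ndarray              # Bonferroni-corrected significance
    alpha: float
    n_tested: int
    degenerate: bool = False


def demean_across_states(values: np.ndarray) -> np.ndarray:
    """Subtract, per connection (and mode), the mean over all states.

    ``values`` is a stack whose first axis indexes states; the result sums
    to zero across states for every remaining index.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two states to demean across states")
    return values - values.mean(axis=0, keepdims=True)


def _fit_two_gaussian_fixed_var(
    x: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM for a 1-D two-component mixture with both variances fixed at 1.

    Means are initialized at the 25th/75th percentiles, weights at 0.5.
    Returns (means, weights, degenerate) with means sorted ascending.
    """
    mu = np.array([np.percentile(x, 25), np.percentile(x, 75)])
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    degenerate = False
    for _ in range(max_iter):
        logp = norm.logpdf(x[:, None], loc=mu[None, :]) + np.log(w)[None, :]
        shift = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - shift)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot[:, 0]) + shift[:, 0]).sum())
        nk = resp.sum(axis=0)
        if nk.min() < 1e-6 * len(x):
            degenerate = True
            break
        mu = (resp * x[:, None]).sum(axis=0) / nk
        w = nk / len(x)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    order = np.argsort(mu)
    return mu[order], w[order], degenerate


def gmm_threshold(values: np.ndarray, alpha: float = 0.001) -> ConnectionTest:
    """Flag significantly coherent connections in one (state, mode) family.

    Each value's p-value is the upper-tail probability under the fitted
    noise (lower-mean) component; the mask applies Bonferroni correction
    over the family (``p * m < alpha``). Degenerate fits fall back to a
    single standard-normal null; identically constant input yields an
    empty mask.
    """
    x = np.asarray(values, dtype=float).ravel()
    m = x.size
    if m < 10:
        raise ValueError(f"need at least 10 values to fit the mixture, got {m}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = mad / 0.6745
    if scale <= 0:
        # all (or more than half) identical: no resolvable structure
        return ConnectionTest(
            values=x,
            standardized=np.zeros_like(x),
            means=np.array([0.0, 0.0]),
            mixture_weights=np.array([1.0, 0.0]),
            pvals=np.ones(m),
            mask=np.zeros(m, dtype=bool),
            alpha=alpha,
            n_tested=m,
            degenerate=True,
        )
    z = (x - med) / scale
    mu, w, degenerate = _fit_two_gaussian_fixed_var(z)
    # calibrate the scale so the noise component really has unit variance:
    # reweight by noise responsibilities, rescale, refit (a few fixed-point steps)
    for _ in range(3):
        if degenerate:
            break
        logp = norm.logpdf(z[:, None], loc=mu[None, :]) + np.log(np.maximum(w, 1e-300))
        resp = np.exp(logp - logp.max(axis=1, keepdims=True))
        resp /= resp.sum(axis=1, keepdims=True)
        r0 = resp[:, 0]
        nv = float((r0 * (z - mu[0]) ** 2).sum() / r0.sum())
        if abs(nv - 1.0) < 1e-3:
            break
        scale *= np.sqrt(nv)
        z = (x - med) / scale
        mu, w, degenerate = _fit_two_gaussian_fixed_var(z)
    if degenerate:
        mu = np.array([z.mean(), z.mean()])
        w = np.array([1.0, 0.0])
    noise_mean = mu[0]
    pvals = norm.sf(z - noise_mean)
    mask = pvals * m < alpha
    return ConnectionTest(
        values=x,
        standardized=z,
        means=mu,
        mixture_weights=w,
        pvals=pvals,
        mask=mask,
        alpha=alpha,
        n_tested=m,
        degenerate=degenerate,
    )
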
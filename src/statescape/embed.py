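"""Time-delay embedding and PCA reduction.

Each parcel time series is expanded into symmetric lagged copies
(a 60 ms window by default), so that a zero-mean Gaussian fit in the
embedded space captures autocovariance — i.e. spectral power and
cross-spectral phase relations. PCA then reduces the embedded dimension
(by default to two components per parcel) before HMM fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


def compute_lags(window_ms: float, fs: float) -> int:
    """Number of lags for an embedding window, promoted to the next odd integer.

    ``round(window_ms / 1000 * fs)`` samples; even counts are promoted so
    the lag list stays symmetric around zero. (60 ms at 250 Hz -> 15.)
    """
    if window_ms <= 0 or fs <= 0:
        raise ValueError("window_ms and fs must be positive")
    n = int(round(window_ms / 1000.0 * fs))
    if n < 1:
        raise ValueError(
            f"embedding window of {window_ms} ms is shorter than one sample at {fs} Hz"
        )
    if n % 2 == 0:
        n += 1
    return n


def make_lag_list(n_lags: int) -> np.ndarray:
    """Symmetric lag offsets ``-(n-1)/2 .. +(n-1)/2`` for odd ``n_lags``."""
    if n_lags < 1 or n_lags % 2 == 0:
        raise ValueError("n_lags must be a positive odd integer")
    h = (n_lags - 1) // 2
    return np.arange(-h, h + 1)


def build_lag_matrix(
    X: np.ndarray, lag_list: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Expand ``X`` (parcels x samples) into a lagged design matrix.

    Row ``t`` of the output holds ``X[p, t + l]`` for every parcel ``p``
    and lag ``l`` (parcel-major, lag-minor column order). Only rows with
    every lag in range are kept, so the output has
    ``n_samples - (n_lags - 1)`` rows.

    Returns
    -------
    embedded : (valid_samples, n_parcels * n_lags) array
    sample_index : int array mapping each embedded row to the original
        sample index it is centered on.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (parcels x samples)")
    lag_list = np.asarray(lag_list, dtype=int)
    P, T = X.shape
    lo, hi = int(lag_list.min()), int(lag_list.max())
    valid = T - (hi - lo)
    if valid < 1:
        raise ValueError(f"trial of {T} samples is shorter than the embedding window")
    centers = np.arange(-lo, -lo + valid)
    cols = []
    for p in range(P):
        for l in lag_list:
            cols.append(X[p, centers + l])
    return np.column_stack(cols), centers


@dataclass
class EmbeddingSpec:
    """Fitted embedding + PCA projection (training statistics included)."""

    n_lags: int
    lag_list: np.ndarray
    n_components: int
    projection: np.ndarray          # (n_embedded, n_components), orthonormal columns
    training_mean: np.ndarray       # per embedded column
    training_scale: np.ndarray      # per embedded column
    explained_variance_ratio: np.ndarray


def fit_pca(embedded_trials: List[np.ndarray], n_components: int) -> EmbeddingSpec:
    """PCA of pooled, per-column standardized embedded rows.

    Standardization statistics are computed over all pooled training rows
    (one group-level model implies shared scaling). The projection is the
    top eigenvectors of the pooled correlation matrix with a deterministic
    sign convention: the largest-magnitude loading of each component is
    made positive.
    """
    Z = np.vstack(embedded_trials)
    n, d = Z.shape
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds embedded dimension {d}")
    if n < n_components:
        raise ValueError("fewer pooled rows than requested components")
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = int(np.flatnonzero(scale == 0)[0])
        raise ValueError(f"zero-variance embedded column {bad}; cannot standardize")
    Zs = (Z - mean) / scale
    cov = (Zs.T @ Zs) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proj = evecs[:, :n_components].copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(proj[:, k])))
        if proj[j, k] < 0:
            proj[:, k] = -proj[:, k]
    evr = evals / evals.sum()
    # lag geometry is attached by the caller; fill from d if unknown
    return EmbeddingSpec(
        n_lags=-1,
        lag_list=np.array([]),
        n_components=n_components,
        projection=proj,
        training_mean=mean,
        training_scale=scale,
        explained_variance_ratio=evr[:n_components],
    )


def apply_pca(spec: EmbeddingSpec, embedded: np.ndarray) -> np.ndarray:
    """Affine application of a fitted spec: standardize, then project."""
    Z = (np.asarray(embedded, dtype=float) - spec.training_mean) / spec.training_scale
    return Z @ spec.projection


def embed_epochs(
    trials: List[np.ndarray], window_ms: float, fs: float, n_pca_per_parcel: int
) -> Tuple[List[np.ndarray], List[np.ndarray], EmbeddingSpec]:
    """Convenience: lag-embed every trial, fit pooled PCA, project.

    Returns (reduced trial matrices, per-trial sample index maps, spec).
    The retained dimension is ``n_pca_per_parcel * n_parcels`` (84 for the
    full-scale 42-parcel configuration).
    """
    n_lags = compute_lags(window_ms, fs)
    lags = make_lag_list(n_lags)
    embedded, maps = [], []
    for X in trials:
        E, idx = build_lag_matrix(X, lags)
        embedded.append(E)
        maps.append(idx)
    n_parcels = trials[0].shape[0]
    spec = fit_pca(embedded, n_components=n_pca_per_parcel * n_parcels)
    spec.n_lags = n_lags
    spec.lag_list = lags
    reduced = [apply_pca(spec, E) for E in embedded]
    return reduced, maps, spec
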
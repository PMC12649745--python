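"""Connectivity manifolds: diffusion-map embedding of region-by-region structure.

Each state's region-by-region connectivity matrix (parcel-space covariance
by default, mode-summed coherence as an alternative) is turned into a
similarity graph over regions, and a diffusion map embeds the regions in a
low-dimensional space where small distance means strong direct-plus-
indirect coupling. Closeness on the manifold is tested with the same
mixture-model machinery used for coherence connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .sigconn import ConnectionTest, demean_across_states, gmm_threshold


@dataclass
class ManifoldEmbedding:
    coords: np.ndarray            # (n_parcels, n_dims): lambda_k^t * psi_k
    eigenvalues: np.ndarray       # nontrivial, descending
    psi: np.ndarray               # all nontrivial right eigenvectors (n_parcels, n-1)
    distances: np.ndarray         # diffusion distances over all nontrivial components
    bandwidth: float
    alpha: float
    t: int


def state_region_similarity(C: np.ndarray) -> np.ndarray:
    """Gaussian affinity between regions' connectivity vectors.

    Region i is represented by row i of the (symmetric) connectivity
    matrix; ``affinity[i, j] = exp(-||v_i - v_j||^2 / eps)`` with the
    self-tuning bandwidth ``eps`` equal to the median squared pairwise
    distance. The diagonal is set to 1.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if np.abs(C - C.T).max() > 1e-8:
        raise ValueError("connectivity matrix must be symmetric")
    n = C.shape[0]
    sq = ((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    off = sq[~np.eye(n, dtype=bool)]
    eps = np.median(off)
    if eps <= 0:
        eps = 1.0  # all rows identical: affinity saturates at 1
    W = np.exp(-sq / eps)
    np.fill_diagonal(W, 1.0)
    return W


def diffusion_map(
    affinity: np.ndarray, n_dims: int = 3, alpha: float = 0.5, t: int = 1
) -> ManifoldEmbedding:
    """Diffusion map of a similarity graph.

    Density-normalized kernel ``W' = D^-alpha W D^-alpha``; random-walk
    operator ``P = D'^-1 W'`` diagonalized through its symmetric conjugate
    for stability. Coordinates are ``lambda_k^t psi_k`` for the top
    ``n_dims`` nontrivial eigenvectors; diffusion distances are Euclidean
    distances using *all* nontrivial components.
    """
    W = np.asarray(affinity, dtype=float)
    n = W.shape[0]
    if (W < 0).any():
        raise ValueError("affinity entries must be non-negative")
    d = W.sum(axis=1)
    if (d <= 0).any():
        bad = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"disconnected graph: node {bad} has zero affinity row")
    Dma = d ** (-alpha)
    W1 = W * Dma[:, None] * Dma[None, :]
    d1 = W1.sum(axis=1)
    dis = 1.0 / np.sqrt(d1)
    S = W1 * dis[:, None] * dis[None, :]
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P; fix sign for reproducibility
    psi = evecs * dis[:, None]
    for k in range(n):
        j = int(np.argmax(np.abs(psi[:, k])))
        if psi[j, k] < 0:
            psi[:, k] = -psi[:, k]
    # drop the trivial (constant, eigenvalue 1) component
    lam = evals[1:]
    psi_nt = psi[:, 1:]
    weighted = psi_nt * np.sign(lam) * (np.abs(lam) ** t)
    coords = weighted[:, :n_dims]
    diff = weighted[:, None, :] - weighted[None, :, :]
    distances = np.sqrt((diff ** 2).sum(axis=2))
    return ManifoldEmbedding(
        coords=coords,
        eigenvalues=lam,
        psi=psi_nt,
        distances=distances,
        bandwidth=float("nan"),
        alpha=alpha,
        t=t,
    )


def manifold_connection_test(
    distances: np.ndarray, alpha: float = 0.001
) -> List[ConnectionTest] | ConnectionTest:
    """Significantly close region pairs on the manifold.

    The closeness score is the negative diffusion distance; given a stack
    of per-state distance matrices the scores are first demeaned across
    states, then each state's scores go through the mixture-model
    threshold (:func:`statescape.sigconn.gmm_threshold`). A single matrix
    is tested directly.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim == 2:
        iu = np.triu_indices(D.shape[0], k=1)
        return gmm_threshold(-D[iu], alpha=alpha)
    if D.ndim != 3:
        raise ValueError("expected a distance matrix or a stack of them")
    iu = np.triu_indices(D.shape[1], k=1)
    closeness = -D[:, iu[0], iu[1]]              # (K, n_pairs)
    demeaned = demean_across_states(closeness)
    return [gmm_threshold(demeaned[k], alpha=alpha) for k in range(D.shape[0])]
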
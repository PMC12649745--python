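#!/usr/bin/env python
"""Diffusion-map connectivity manifolds per fitted state.

Builds each state's parcel-space covariance from gamma-weighted second
moments, embeds the regions with a diffusion map, and tests which region
pairs are significantly close on the manifold (same mixture-model test as
for coherence, after demeaning across states).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, get_dataset, get_fit

from statescape.manifold import diffusion_map, manifold_connection_test, state_region_similarity


def main():
    scene, epochs, truths = get_dataset()
    fit = get_fit()
    probs, maps = fit["probs"], fit["maps"]
    K, P = scene.K_true, epochs.n_parcels
    num = np.zeros((K, P, P))
    den = np.zeros(K)
    for X, g, idx in zip(epochs.trials, probs.gammas, maps):
        Xv = X[:, idx]
        for k in range(K):
            num[k] += (Xv * g[:, k]) @ Xv.T
            den[k] += g[:, k].sum()
    covs = num / den[:, None, None]

    embeddings = [diffusion_map(state_region_similarity(covs[k])) for k in range(K)]
    rows = []
    for k, emb in enumerate(embeddings):
        for p in range(P):
            rows.append({"state": k, "parcel": epochs.parcel_labels[p],
                         **{f"dim{d + 1}": emb.coords[p, d] for d in range(3)}})
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "manifold_coordinates.tsv", sep="\t",
                              index=False, float_format="%.6f")

    dist_stack = np.stack([e.distances for e in embeddings])
    tests = manifold_connection_test(dist_stack, alpha=0.001)
    iu = np.triu_indices(P, k=1)
    close = []
    for k, res in enumerate(tests):
        for idx in np.flatnonzero(res.mask):
            close.append({"state": k, "parcel_i": int(iu[0][idx]),
                          "parcel_j": int(iu[1][idx]),
                          "closeness": float(res.values[idx]),
                          "p": float(res.pvals[idx])})
    pd.DataFrame(close, columns=["state", "parcel_i", "parcel_j", "closeness", "p"]
                 ).to_csv(RESULTS / "manifold_close_pairs.tsv", sep="\t",
                          index=False, float_format="%.5g")
    spreads = [float(np.median(e.distances[np.triu_indices(P, 1)])) for e in embeddings]
    for k, s in enumerate(spreads):
        print(f"state {k}: median manifold distance {s:.4f}, "
              f"{sum(c['state'] == k for c in close)} significantly close pairs")
    print(f"wrote {RESULTS / 'manifold_coordinates.tsv'} and manifold_close_pairs.tsv")


if __name__ == "__main__":
    main()
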
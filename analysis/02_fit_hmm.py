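#!/usr/bin/env python
"""Fit the TDE-HMM to the simulated dataset and score ground-truth recovery.

Embeds every trial (60 ms window, 2 PCA components per parcel), fits one
zero-mean Gaussian HMM across all trials, aligns fitted states to the
generating states, and reports transition-matrix error and state-time-
course agreement.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, get_dataset, get_fit


def main():
    scene, epochs, truths = get_dataset()
    fit = get_fit()
    perm = fit["perm"]
    counts = np.zeros((scene.K_true, scene.K_true))
    for s in truths:
        np.add.at(counts, (s[:-1], s[1:]), 1.0)
    A_target = counts / counts.sum(axis=1, keepdims=True)
    Ahat = fit["params"].A[np.ix_(perm, perm)]
    G = np.vstack(fit["probs"].gammas)[:, perm]
    truth_cat = np.concatenate([s[m] for s, m in zip(truths, fit["maps"])])
    agree = (np.argmax(G, axis=1) == truth_cat).mean()

    rows = [{"from_state": j, "to_state": k,
             "pooled_truth": A_target[j, k], "fitted": Ahat[j, k]}
            for j in range(scene.K_true) for k in range(scene.K_true)]
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "hmm_recovery.tsv", sep="\t", index=False, float_format="%.5f")
    print(f"log-likelihood: {fit['diag']['loglik']:.1f} "
          f"({fit['diag']['n_iter']} EM iterations per restart)")
    print(f"transition-matrix MAE vs pooled truth: "
          f"{np.abs(Ahat - A_target).mean():.4f}")
    print(f"state time-course agreement (posterior argmax vs truth): {agree:.3f}")
    print(f"wrote {RESULTS / 'hmm_recovery.tsv'}")


if __name__ == "__main__":
    main()
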
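"""Shared plumbing for the analysis drivers.

The study dataset is the default synthetic scene (10 parcels, 100 Hz,
3 states, 40 trials x 2 conditions x 10 participants) with a planted
+0.15 increase of the 0->1 transition in condition B. Heavy intermediates
(the dataset and the HMM fit) are cached under scratch/ so the numbered
scripts can be run independently; result tables go to results/.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from statescape import default_scene, simulate_epochs
from statescape.embed import embed_epochs
from statescape.hmm import align_states, em_fit, viterbi

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 11


def get_dataset():
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / "dataset.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    scene = default_scene()
    epochs, truths = simulate_epochs(scene, 40, participants=10, seed=SEED)
    payload = (scene, epochs, truths)
    with open(cache, "wb") as fh:
        pickle.dump(payload, fh)
    return payload


def get_fit():
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / "fit.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    scene, epochs, truths = get_dataset()
    reduced, maps, spec = embed_epochs(epochs.trials, 60, scene.fs, 2)
    params, probs, diag = em_fit(
        reduced, K=scene.K_true, n_restarts=3, max_iter=60, tol=1e-6, seed=5
    )
    onehot = [np.eye(scene.K_true)[s[m]] for s, m in zip(truths, maps)]
    perm = align_states(np.vstack(onehot), np.vstack(probs.gammas))
    paths = [viterbi(Y, params) for Y in reduced]
    payload = dict(spec=spec, maps=maps, params=params, probs=probs,
                   diag=diag, perm=perm, paths=paths)
    with open(cache, "wb") as fh:
        pickle.dump(payload, fh)
    return payload
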
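import numpy as np
import pytest

from statescape import (
    GroundTruthScene,
    PipelineConfig,
    default_scene,
    simulate_epochs,
)
from statescape.embed import embed_epochs
from statescape.hmm import align_states, em_fit, viterbi


@pytest.fixture(scope="session")
def tiny_scene():
    """Two-state, six-parcel scene small enough for full pipeline runs."""
    return GroundTruthScene(
        n_parcels=6,
        fs=100.0,
        epoch_length_s=2.0,
        K_true=2,
        state_specs=[[(0, 1, 10.0, 0.9)], [(2, 3, 30.0, 0.9)]],
        condition_B_delta={(0, 1): 0.15},
    )


@pytest.fixture(scope="session")
def tiny_epochs(tiny_scene):
    epochs, truths = simulate_epochs(
        tiny_scene, n_trials_per_condition=4, participants=4, seed=1
    )
    return epochs, truths


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tiny_epochs):
    """The full pipeline run twice with one seed on the tiny scene."""
    from statescape.pipeline import result_manifest, run_pipeline

    epochs, _ = tiny_epochs
    cfg = PipelineConfig(
        n_states=2, n_restarts=2, max_iter=25, n_permutations=150, seed=3
    )
    r1 = run_pipeline(cfg, epochs)
    r2 = run_pipeline(cfg, epochs)
    return r1, r2, result_manifest(r1), result_manifest(r2)


@pytest.fixture(scope="session")
def recovery_fit():
    """Full TDE-HMM fit of the default synthetic scene with known truth.

    Shared by the parameter-recovery tests; one EM fit over 800 trials.
    """
    scene = default_scene()
    epochs, truths = simulate_epochs(
        scene, n_trials_per_condition=40, participants=10, seed=11
    )
    reduced, maps, spec = embed_epochs(
        epochs.trials, window_ms=60, fs=scene.fs, n_pca_per_parcel=2
    )
    params, probs, diag = em_fit(
        reduced, K=scene.K_true, n_restarts=3, max_iter=60, tol=1e-6, seed=5
    )
    onehot = [np.eye(scene.K_true)[s[m]] for s, m in zip(truths, maps)]
    perm = align_states(np.vstack(onehot), np.vstack(probs.gammas))
    paths = [viterbi(Y, params) for Y in reduced]
    return {
        "scene": scene,
        "epochs": epochs,
        "truths": truths,
        "reduced": reduced,
        "maps": maps,
        "spec": spec,
        "params": params,
        "probs": probs,
        "diag": diag,
        "perm": perm,
        "paths": paths,
    }
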
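"""End-to-end orchestration: embed -> HMM -> spectra -> connections ->
manifolds -> dynamics -> decoding.

Every stage draws its randomness from the single root seed through the
named-stage scheme in :mod:`statescape.containers`, so a full run is
deterministic given (config, data) and single stages can be reproduced in
isolation.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import decode as _decode
from . import dynstats as _dyn
from . import manifold as _mani
from . import sigconn as _sig
from . import spectra as _spec
from .containers import EpochSet, PipelineConfig, stage_seed
from .embed import EmbeddingSpec, embed_epochs
from .hmm import HMMParams, StateProbs, em_fit, viterbi

log = logging.getLogger("statescape")


@dataclass
class PipelineResult:
    config: PipelineConfig
    embedding: EmbeddingSpec
    sample_maps: List[np.ndarray]
    params: HMMParams
    probs: StateProbs
    fit_diagnostics: Dict
    viterbi_paths: List[np.ndarray]
    spectra: Optional[_spec.StateSpectra]
    modes: Optional[_spec.FrequencyModes]
    mode_coefficients: Optional[np.ndarray]
    mode_coherence: Optional[np.ndarray]          # (K, M, P, P)
    connection_tests: Optional[List[List[_sig.ConnectionTest]]]   # [state][mode]
    state_covariances: np.ndarray                 # parcel-space, (K, P, P)
    manifolds: List[_mani.ManifoldEmbedding]
    manifold_tests: Optional[List[_sig.ConnectionTest]]
    dynamics: List[_dyn.TrialDynamics]
    transition_test: _dyn.TransitionTestResult
    temporal_tests: Dict[str, Dict[str, pd.DataFrame]]
    decoding: Optional[_decode.DecodingResult]
    decoding_clusters: Optional[Dict]
    timings_s: Dict[str, float] = field(default_factory=dict)


def _timed(timings: Dict[str, float], name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            timings[name] = time.perf_counter() - self.t0
            log.info("stage %s: done in %.2f s", name, timings[name])

    return _T()


def _stage(fn, name):
    try:
        return fn()
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e


def run_pipeline(config: PipelineConfig, epochs: EpochSet) -> PipelineResult:
    """Run the full analysis on an epoch set. Deterministic given
    (config.seed, epochs)."""
    log.info("config: %s", config.to_dict())
    timings: Dict[str, float] = {}
    K = config.n_states
    fs = epochs.fs

    with _timed(timings, "embed"):
        reduced, maps, spec = _stage(
            lambda: embed_epochs(
                epochs.trials, config.embed_window_ms, fs, config.n_pca_per_parcel
            ),
            "embed",
        )

    with _timed(timings, "hmm"):
        params, probs, diag = _stage(
            lambda: em_fit(
                reduced,
                K,
                n_restarts=config.n_restarts,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=stage_seed(config.seed, "hmm"),
                ridge=config.cov_ridge,
            ),
            "hmm",
        )
        paths = [viterbi(Y, params) for Y in reduced]

    with _timed(timings, "spectra"):
        spectra = _stage(
            lambda: _spec.state_cross_spectra(
                epochs.trials,
                probs.gammas,
                maps,
                fs,
                nperseg=config.spectra_nperseg,
                overlap=config.spectra_overlap,
            ),
            "spectra",
        )
        iu = np.triu_indices(epochs.n_parcels, k=1)
        stack = spectra.coh[:, :, iu[0], iu[1]]           # (K, F, n_pairs)
        stack = np.transpose(stack, (0, 2, 1)).reshape(-1, spectra.freqs.size)
        n_modes = min(config.nnmf_modes, spectra.freqs.size - 1)
        modes, coeffs = _stage(
            lambda: _spec.nnmf_modes(
                stack, spectra.freqs, n_modes=n_modes,
                seed=stage_seed(config.seed, "nnmf"),
            ),
            "spectra",
        )
        mode_coh = _spec.project_to_modes(spectra, modes)

    with _timed(timings, "sigconn"):
        conn_tests: Optional[List[List[_sig.ConnectionTest]]] = None
        if K >= 2 and iu[0].size >= 10:
            pair_vals = mode_coh[:, :, iu[0], iu[1]]       # (K, M, n_pairs)
            demeaned = _sig.demean_across_states(pair_vals)
            conn_tests = [
                [
                    _sig.gmm_threshold(demeaned[k, m], alpha=config.gmm_alpha)
                    for m in range(demeaned.shape[1])
                ]
                for k in range(K)
            ]

    with _timed(timings, "manifold"):
        state_cov = _parcel_state_covariances(epochs, probs, maps)
        manifolds = [
            _stage(
                lambda S=state_cov[k]: _mani.diffusion_map(
                    _mani.state_region_similarity(S),
                    n_dims=config.manifold_ndims,
                    alpha=config.manifold_alpha,
                    t=config.manifold_t,
                ),
                "manifold",
            )
            for k in range(K)
        ]
        mani_tests = None
        if K >= 2 and epochs.n_parcels * (epochs.n_parcels - 1) // 2 >= 10:
            dist_stack = np.stack([m.distances for m in manifolds])
            mani_tests = _stage(
                lambda: _mani.manifold_connection_test(dist_stack, alpha=config.gmm_alpha),
                "manifold",
            )

    with _timed(timings, "dynstats"):
        dynamics = _dyn.trial_dynamics(
            probs.xi_sums,
            probs.gammas,
            paths,
            fs,
            epochs.participants(),
            epochs.conditions(),
            K,
        )
        if K >= 2 and len(epochs.condition_levels) == 2:
            ttest = _stage(
                lambda: _dyn.permutation_test_transitions(
                    dynamics,
                    n_perm=config.n_permutations,
                    q=config.fdr_q,
                    seed=stage_seed(config.seed, "permutation"),
                ),
                "dynstats",
            )
        else:
            ttest = _dyn.TransitionTestResult(
                pairs=[], obs_diff=np.zeros(0), pvals={}, rejected={},
                n_permutations=config.n_permutations, q=config.fdr_q,
                seed=stage_seed(config.seed, "permutation"),
            )
        temporal: Dict[str, Dict[str, pd.DataFrame]] = {}
        if len(epochs.condition_levels) == 2 and len(set(epochs.participants())) >= 3:
            for metric in ("lifetime", "fo", "switch_rate"):
                cells = _metric_cell_means(dynamics, metric, K)
                temporal[metric] = _stage(
                    lambda c=cells, m=metric: _dyn.temporal_metric_comparison(
                        c, m, n_perm=min(config.n_permutations, 5000),
                        q=config.fdr_q,
                        seed=stage_seed(config.seed, f"temporal-{metric}"),
                    ),
                    "dynstats",
                )

    with _timed(timings, "decode"):
        decoding = None
        clusters = None
        if len(epochs.condition_levels) == 2:
            feats, edges = _stage(
                lambda: _decode.bin_gammas(
                    probs.gammas, fs, config.decode_window_ms, config.decode_bin_ms
                ),
                "decode",
            )
            decoding = _stage(
                lambda: _decode.lasso_logistic_cv(
                    feats,
                    epochs.conditions(),
                    epochs.participants(),
                    seed=stage_seed(config.seed, "decode"),
                    bin_edges_s=edges,
                ),
                "decode",
            )
            n_bins = len(edges) - 1
            clusters = _stage(
                lambda: _decode.cluster_permutation_significance(
                    feats,
                    epochs.conditions(),
                    epochs.participants(),
                    n_bins,
                    n_perm=max(100, min(config.n_permutations, 200)),
                    seed=stage_seed(config.seed, "decode-cluster"),
                ),
                "decode",
            )

    return PipelineResult(
        config=config,
        embedding=spec,
        sample_maps=maps,
        params=params,
        probs=probs,
        fit_diagnostics=diag,
        viterbi_paths=paths,
        spectra=spectra,
        modes=modes,
        mode_coefficients=coeffs,
        mode_coherence=mode_coh,
        connection_tests=conn_tests,
        state_covariances=state_cov,
        manifolds=manifolds,
        manifold_tests=mani_tests,
        dynamics=dynamics,
        transition_test=ttest,
        temporal_tests=temporal,
        decoding=decoding,
        decoding_clusters=clusters,
        timings_s=timings,
    )


def _parcel_state_covariances(
    epochs: EpochSet, probs: StateProbs, maps: List[np.ndarray]
) -> np.ndarray:
    """Gamma-weighted second moments of the raw parcel signals, per state."""
    K = probs.K
    P = epochs.n_parcels
    num = np.zeros((K, P, P))
    den = np.zeros(K)
    for X, g, idx in zip(epochs.trials, probs.gammas, maps):
        Xv = X[:, idx]
        for k in range(K):
            num[k] += (Xv * g[:, k]) @ Xv.T
            den[k] += g[:, k].sum()
    den[den == 0] = 1.0
    return num / den[:, None, None]


def _metric_cell_means(
    dynamics: List[_dyn.TrialDynamics], metric: str, K: int
) -> pd.DataFrame:
    rows = []
    keyed: Dict = {}
    for d in dynamics:
        keyed.setdefault((d.participant_id, d.condition), []).append(d)
    for (pid, cond), ds in keyed.items():
        if metric == "switch_rate":
            rows.append(
                {"participant": pid, "condition": cond, "state": 0,
                 "value": float(np.mean([d.switch_rate for d in ds]))}
            )
            continue
        for k in range(K):
            if metric == "fo":
                v = float(np.mean([d.fo[k] for d in ds]))
            else:  # lifetime
                lts = np.concatenate([d.lifetimes_s[k] for d in ds])
                v = float(lts.mean()) if lts.size else 0.0
            rows.append({"participant": pid, "condition": cond, "state": k, "value": v})
    return pd.DataFrame(rows)


def result_manifest(result: PipelineResult) -> Dict:
    """Canonical, JSON-able summary with array digests for determinism checks."""

    def dig(a: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]

    man = {
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "pi": dig(result.params.pi),
        "A": dig(result.params.A),
        "state_cov": dig(result.params.state_cov),
        "gammas": dig(np.vstack(result.probs.gammas)),
        "viterbi": dig(np.concatenate(result.viterbi_paths)),
        "loglik": float(result.probs.logliks.sum()),
        "state_covariances_parcel": dig(result.state_covariances),
        "manifold_coords": dig(np.stack([m.coords for m in result.manifolds])),
        "transition_obs_diff": dig(result.transition_test.obs_diff),
    }
    if result.spectra is not None:
        man["coherence"] = dig(result.spectra.coh)
        man["mode_weights"] = dig(result.modes.weights)
    if result.decoding is not None:
        man["decode_fold_accuracy"] = dig(result.decoding.fold_accuracy)
        man["decode_mean_accuracy"] = result.decoding.mean_accuracy
    for lv, p in result.transition_test.pvals.items():
        man[f"transition_p_{lv}"] = dig(p)
    return man
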
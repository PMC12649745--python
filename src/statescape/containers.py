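"""Core data containers, configuration, and the seed-splitting scheme."""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


@dataclass
class TrialMeta:
    """Per-trial metadata record.

    Attributes
    ----------
    participant_id : str
        Identifier of the participant the trial belongs to.
    condition : str
        One of exactly two condition labels (e.g. perceptual outcome
        "correct" / "incorrect").
    t0_offset_s : float
        Epoch start relative to the stimulus event, in seconds
        (negative for prestimulus epochs).
    """

    participant_id: str
    condition: str
    t0_offset_s: float = 0.0


class EpochSet:
    """Trial-structured multichannel time series with metadata.

    Every analysis stage consumes this container: a list of
    ``n_parcels x n_samples`` matrices (one per trial), a common sampling
    rate, parcel labels and per-trial metadata.

    Invariants enforced at construction:

    * all trials share ``n_parcels``;
    * ``n_samples`` may vary by at most one sample across trials;
    * ``fs > 0``;
    * condition labels are drawn from at most two distinct values.
    """

    def __init__(
        self,
        trials: Sequence[np.ndarray],
        fs: float,
        parcel_labels: Sequence[str],
        trial_meta: Sequence[TrialMeta],
    ):
        if fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {fs}")
        trials = [np.asarray(t, dtype=float) for t in trials]
        if len(trials) == 0:
            raise ValueError("EpochSet needs at least one trial")
        if len(trials) != len(trial_meta):
            raise ValueError(
                f"{len(trials)} trials but {len(trial_meta)} metadata records"
            )
        n_parcels = trials[0].shape[0]
        if n_parcels != len(parcel_labels):
            raise ValueError(
                f"trial 0 has {n_parcels} rows but {len(parcel_labels)} parcel labels"
            )
        lengths = []
        for i, t in enumerate(trials):
            if t.ndim != 2:
                raise ValueError(f"trial {i}: expected 2-D matrix, got ndim={t.ndim}")
            if t.shape[0] != n_parcels:
                raise ValueError(
                    f"trial {i}: {t.shape[0]} parcels, expected {n_parcels}"
                )
            lengths.append(t.shape[1])
        if max(lengths) - min(lengths) > 1:
            raise ValueError(
                "trial lengths differ by more than one sample "
                f"(min={min(lengths)}, max={max(lengths)}); refusing to truncate silently"
            )
        conditions = sorted({m.condition for m in trial_meta})
        if len(conditions) > 2:
            raise ValueError(f"more than two condition labels: {conditions}")
        self.trials = trials
        self.fs = float(fs)
        self.parcel_labels = list(parcel_labels)
        self.trial_meta = list(trial_meta)
        self.condition_levels = conditions

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_parcels(self) -> int:
        return self.trials[0].shape[0]

    def conditions(self) -> np.ndarray:
        return np.array([m.condition for m in self.trial_meta])

    def participants(self) -> np.ndarray:
        return np.array([m.participant_id for m in self.trial_meta])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EpochSet(n_trials={self.n_trials}, n_parcels={self.n_parcels}, "
            f"fs={self.fs}, conditions={self.condition_levels})"
        )


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults follow the standard TDE-HMM analysis: a 60 ms embedding
    window, PCA retaining two components per parcel, six states, 5,000
    permutations for the transition test, Bonferroni alpha 0.001 for the
    mixture-model connection test, and a 600 ms decoding window at 60 ms
    resolution.
    """

    embed_window_ms: float = 60.0
    n_pca_per_parcel: int = 2
    n_states: int = 6
    n_restarts: int = 5
    max_iter: int = 100
    tol: float = 1e-5
    n_permutations: int = 5000
    fdr_q: float = 0.05
    gmm_alpha: float = 0.001
    decode_window_ms: float = 600.0
    decode_bin_ms: float = 60.0
    seed: int = 0
    # numerical / estimator details
    cov_ridge: float = 1e-6
    spectra_nperseg: int = 64
    spectra_overlap: float = 0.5
    nnmf_modes: int = 4
    manifold_ndims: int = 3
    manifold_alpha: float = 0.5
    manifold_t: int = 1

    def __post_init__(self):
        for name in ("n_pca_per_parcel", "n_states", "n_restarts", "max_iter",
                     "n_permutations", "nnmf_modes", "manifold_ndims"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not 0 < self.gmm_alpha < 1:
            raise ValueError("gmm_alpha must lie in (0, 1)")
        if self.embed_window_ms <= 0 or self.decode_window_ms <= 0 or self.decode_bin_ms <= 0:
            raise ValueError("window lengths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the single root seed.

    The scheme is fixed and documented: the stage name is hashed with
    CRC-32 and combined with the root seed through a
    ``numpy.random.SeedSequence``, whose first 31-bit word is returned.
    Re-running a single stage therefore reproduces exactly the stream it
    had inside a full pipeline run.
    """
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded by the named-stage scheme (see :func:`stage_seed`)."""
    return np.random.default_rng(stage_seed(root_seed, stage))
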
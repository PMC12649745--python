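"""Reading/writing the epoch container and result tables.

The on-disk epoch container is deliberately plain: one delimited-text
matrix per trial plus a single ``meta.json`` naming the sampling rate,
parcel labels and per-trial records. Converters from neurophysiology
formats (FIF, EDF, ...) are an extension point, not core.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .containers import EpochSet, TrialMeta

META_NAME = "meta.json"


def write_epochs(epochs: EpochSet, path) -> Path:
    """Write an :class:`EpochSet` as a directory of TSV matrices + ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (trial, meta) in enumerate(zip(epochs.trials, epochs.trial_meta)):
        fname = f"trial_{i:04d}.tsv"
        np.savetxt(path / fname, trial, delimiter="\t", fmt="%.17g")
        records.append(
            {
                "file": fname,
                "participant_id": meta.participant_id,
                "condition": meta.condition,
                "t0_offset_s": meta.t0_offset_s,
            }
        )
    meta = {
        "fs": epochs.fs,
        "parcel_labels": epochs.parcel_labels,
        "condition_levels": epochs.condition_levels,
        "trials": records,
    }
    with open(path / META_NAME, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_epochs(path) -> EpochSet:
    """Read the directory container written by :func:`write_epochs`.

    Validation failures name the offending trial file.
    """
    path = Path(path)
    meta_path = path / META_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    fs = meta["fs"]
    parcel_labels = meta["parcel_labels"]
    levels = set(meta.get("condition_levels") or [])
    trials, trial_meta = [], []
    for rec in meta["trials"]:
        fpath = path / rec["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"trial file listed in metadata is missing: {fpath}")
        X = np.loadtxt(fpath, delimiter="\t", ndmin=2)
        if X.shape[0] != len(parcel_labels):
            raise ValueError(
                f"{fpath}: matrix has {X.shape[0]} rows, metadata names "
                f"{len(parcel_labels)} parcels"
            )
        if levels and rec["condition"] not in levels:
            raise ValueError(
                f"{fpath}: unknown condition label {rec['condition']!r} "
                f"(expected one of {sorted(levels)})"
            )
        trials.append(X)
        trial_meta.append(
            TrialMeta(rec["participant_id"], rec["condition"], rec.get("t0_offset_s", 0.0))
        )
    return EpochSet(trials, fs, parcel_labels, trial_meta)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict:
    """Emit named result tables as TSV and return (and write) a JSON manifest.

    The manifest lists each file with a SHA-256 digest of its contents,
    plus a hash of the configuration and the seed, so that two runs can
    be compared for bit-identity.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        if any(c in name for c in "/\\\0"):
            raise ValueError(f"table name {name!r} is not filesystem-safe")
        fname = f"{name}.tsv"
        table = pd.DataFrame(table)
        table.to_csv(path / fname, sep="\t", index=False, float_format="%.12g")
        digest = hashlib.sha256((path / fname).read_bytes()).hexdigest()
        entries.append({"name": name, "file": fname, "sha256": digest,
                        "n_rows": int(table.shape[0]), "n_cols": int(table.shape[1])})
    cfg_hash = None
    if config is not None:
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
    manifest = {"files": entries, "config_hash": cfg_hash, "seed": seed}
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
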
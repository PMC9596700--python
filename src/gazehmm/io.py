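"""Fixation CSV interchange, run configs and small I/O utilities.

The fixation CSV follows the field's toolbox conventions: one row per
fixation with columns ``subject_id, trial_id, fixation_index, x, y,
duration_ms, scale`` (the last two optional on input), 1-based
contiguous fixation indices within a trial, and 0-based pixel
coordinates with the origin at the top-left.  Writers are atomic
(temp file + rename) and deterministic in row order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import pathlib
import tempfile
import warnings

import numpy as np
import pandas as pd
import yaml

from .gaze import Fixation, FixationSequence, scale_weights
from .training import TrainConfig

__all__ = [
    "read_fixation_csv",
    "write_fixation_csv",
    "RunConfig",
    "atomic_write_text",
    "write_manifest",
]

_REQUIRED_COLUMNS = ("subject_id", "trial_id", "fixation_index", "x", "y")
_ALL_COLUMNS = ("subject_id", "trial_id", "fixation_index", "x", "y", "duration_ms", "scale")


def read_fixation_csv(path, max_fixations: int | None = None) -> dict:
    """Read fixation records into per-subject lists of FixationSequence.

    Rows are grouped by (subject, trial) and ordered by fixation index;
    ``max_fixations`` truncates each trial (the usual analysis keeps
    the first three fixations).  Non-contiguous indices produce a
    warning and are re-indexed.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"fixation CSV missing required column {col!r}")
    out: dict = {}
    if df.empty:
        return out
    has_scale = "scale" in df.columns and df["scale"].notna().any()
    for (subject, trial), g in df.groupby(["subject_id", "trial_id"], sort=True):
        g = g.sort_values("fixation_index")
        idx = g["fixation_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            warnings.warn(
                f"non-contiguous fixation indices for subject {subject!r} trial {trial}; re-indexing"
            )
        if max_fixations is not None:
            g = g.head(max_fixations)
        fixations = []
        for row in g.itertuples(index=False):
            s = float(row.scale) if has_scale and np.isfinite(getattr(row, "scale", np.nan)) else 1.0
            fixations.append(
                Fixation(
                    location=np.array([row.x, row.y], dtype=float),
                    scale_weights=scale_weights(s),
                    scale=s if has_scale else np.nan,
                )
            )
        out.setdefault(str(subject), []).append(
            FixationSequence(fixations=fixations, trial_id=int(trial))
        )
    return out


def write_fixation_csv(sequences_by_subject: dict, path) -> None:
    """Write per-subject fixation sequences as a deterministic CSV.

    Rows are ordered by (subject, trial, fixation index); floats use
    repr round-trip precision so a read-back reproduces the values.
    """
    rows = []
    for subject in sorted(sequences_by_subject):
        for seq in sorted(sequences_by_subject[subject], key=lambda s: s.trial_id):
            for i, fx in enumerate(seq.fixations, start=1):
                rows.append(
                    dict(
                        subject_id=subject,
                        trial_id=seq.trial_id,
                        fixation_index=i,
                        x=repr(float(fx.location[0])),
                        y=repr(float(fx.location[1])),
                        duration_ms="",
                        scale="" if np.isnan(fx.scale) else repr(float(fx.scale)),
                    )
                )
    text = ",".join(_ALL_COLUMNS) + "\n"
    for row in rows:
        text += ",".join(str(row[c]) for c in _ALL_COLUMNS) + "\n"
    atomic_write_text(path, text)


def atomic_write_text(path, text: str) -> None:
    path = pathlib.Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclasses.dataclass
class RunConfig:
    """Full run configuration: training + stimulus + analysis settings."""

    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    exemplars_per_identity: int = 20
    stimulus_noise_sd: float = 0.03
    n_individuals: int = 80
    n_replicates: int = 10
    n_trials: int = 50
    k_range: tuple = (1, 6)
    hmm_restarts: int = 100
    cluster_restarts: int = 100
    n_virtual_samples: int = 100
    out_dir: str = "runs"

    _TRAIN_KEYS = frozenset(f.name for f in dataclasses.fields(TrainConfig))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        own = {f.name for f in dataclasses.fields(cls)} - {"train"}
        train_kwargs = dict(raw.pop("train", {}) or {})
        unknown = (set(raw) - own) | (set(train_kwargs) - cls._TRAIN_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("checkpoint_epochs", "fixation_weights"):
            if key in train_kwargs:
                train_kwargs[key] = tuple(train_kwargs[key])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(train=TrainConfig(**train_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"] = self.train.to_dict()
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def write_manifest(out_dir, config, seed: int, extra: dict | None = None) -> pathlib.Path:
    """Write a reproducibility manifest (config, seed, package version)."""
    from . import __version__

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(
        package="gazehmm",
        version=__version__,
        seed=int(seed),
        config=config.to_dict() if hasattr(config, "to_dict") else config,
    )
    try:
        import subprocess

        manifest["git_hash"] = (
            subprocess.run(
                ["git", "rev-parse", "HEAD"], capture_output=True, text=True, timeout=5
            ).stdout.strip()
            or None
        )
    except Exception:
        manifest["git_hash"] = None
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=1, default=str))
    return path
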
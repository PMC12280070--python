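"""Trial CSV dialect, manifests and run configuration.

The trial table is a plain UTF-8 CSV with one row per trial and columns
subject, phase, block, trial, pair_id, condition, option_left,
option_right, choice, outcome. Test rows carry an empty outcome. The
``condition`` column holds the learning condition for learning rows and
the pair type (GvG/BvB/GvB) for test rows. A column-mapping config adapts
externally deposited tables with different headers onto this dialect.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import TRIAL_COLUMNS, BehaviorDataset
from .designs import ExperimentDesign, get_design

CSV_COLUMNS = [
    "subject",
    "phase",
    "block",
    "trial",
    "pair_id",
    "condition",
    "option_left",
    "option_right",
    "choice",
    "outcome",
]


def write_trials(dataset: BehaviorDataset, path) -> None:
    df = dataset.trials[CSV_COLUMNS].copy()
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(
    path,
    design: ExperimentDesign | str,
    column_map: dict | None = None,
) -> BehaviorDataset:
    """Read and validate a trial CSV against a design.

    ``column_map`` renames external column names onto the dialect (e.g.
    ``{"sub": "subject"}``). Raises with offending row numbers on test
    rows that carry outcomes, unknown option ids, or choices that match
    neither shown option.
    """
    if isinstance(design, str):
        design = get_design(design)
    df = pd.read_csv(path, encoding="utf-8")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df[CSV_COLUMNS].copy()

    bad = df.index[(df["phase"] == "test") & df["outcome"].notna()]
    if len(bad):
        raise ValueError(f"test rows with outcomes at rows {list(bad[:10])}")
    known = set(design.option_ids())
    ids = pd.concat([df["option_left"], df["option_right"]])
    unknown = sorted(set(ids) - known)
    if unknown:
        raise ValueError(f"unknown option ids: {unknown[:10]}")
    bad = df.index[(df["choice"] != df["option_left"]) & (df["choice"] != df["option_right"])]
    if len(bad):
        raise ValueError(f"choice matches neither option at rows {list(bad[:10])}")

    df["pair_type"] = np.where(df["phase"] == "learning", "learning", df["condition"])
    dataset = BehaviorDataset(trials=df[TRIAL_COLUMNS], design=design)
    dataset.validate()
    return dataset


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


DEFAULT_CONFIG = {
    "design": "main",
    "models": None,  # None -> all twelve
    "n_subjects": 20,
    "phase": "learning",
    "n_restarts": 10,
    "n_permutations": 1000,
    "prior_variance_scale": 1.0,
    "seed": 0,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
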
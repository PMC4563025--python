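"""Readers and writers for the pipeline's delimited tables and configs.

All tables are UTF-8 CSV with a header row; outputs carry a comment header
recording the generating configuration hash for provenance. Trial tables
are validated on read: required columns, numeric predictions, unique
(participant, condition, trial) keys, contiguous 1..42 condition-local
trial indices.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialTableError",
    "read_trial_table",
    "write_table",
    "read_table",
    "load_config",
    "save_config",
    "config_hash",
]

REQUIRED_COLUMNS = [
    "participant_id",
    "session",
    "condition_id",
    "sd_level",
    "sd_target",
    "ev",
    "trial_in_condition",
    "reward",
    "prediction",
]


class TrialTableError(ValueError):
    """Malformed trial table."""


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> Path:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level prediction dataset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path}: empty file") from None
    if df.empty:
        raise TrialTableError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")

    bad = pd.to_numeric(df["prediction"], errors="coerce").isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]
        raise TrialTableError(f"{path}: non-numeric predictions at lines {lines}")
    df["prediction"] = pd.to_numeric(df["prediction"])

    key = ["participant_id", "condition_id", "trial_in_condition"]
    dupes = df.duplicated(key, keep=False)
    if dupes.any():
        first = df.loc[dupes, key].iloc[0].tolist()
        raise TrialTableError(f"{path}: duplicated trial key {tuple(first)}")

    for (pid, cid), grp in df.groupby(["participant_id", "condition_id"]):
        trials = np.sort(grp["trial_in_condition"].to_numpy())
        expected = np.arange(1, len(trials) + 1)
        if not np.array_equal(trials, expected):
            raise TrialTableError(
                f"{path}: participant {pid} condition {cid} has non-contiguous "
                f"trial indices"
            )
    return df



def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text) or {}
    return json.loads(text)


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str), encoding="utf-8")
    return path
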
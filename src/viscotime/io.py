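"""Trial-table I/O and session configuration.

Trial tables are plain CSV with the fixed header
(subject, task, block, viscosity, duration_s, choice, rt_s, ts_s, tp_s,
move_distance_m, force_n); fields not applicable to a task are left
empty.  Files written here carry the seed and a configuration hash in a
leading comment line so every output is traceable to its generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import SessionConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "load_config",
    "config_hash",
]

TRIAL_COLUMNS = (
    "subject",
    "task",
    "block",
    "viscosity",
    "duration_s",
    "choice",
    "rt_s",
    "ts_s",
    "tp_s",
    "move_distance_m",
    "force_n",
)

_REQUIRED = {
    "categorization": ("duration_s", "choice", "rt_s"),
    "reproduction": ("ts_s", "tp_s"),
}


def config_hash(config: object) -> str:
    """Short deterministic hash of any JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_trials(
    trials: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: object | None = None,
) -> Path:
    """Write a trial table as CSV (numbers at 9 significant digits).

    A leading ``#`` comment embeds the seed and config hash; readers here
    skip it transparently.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = trials.reindex(columns=list(TRIAL_COLUMNS))
    with open(path, "w") as fh:
        meta = {"seed": seed, "config_hash": config_hash(config) if config else None}
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return path


def read_trials(path: str | Path, task: str) -> pd.DataFrame:
    """Read and validate a trial table for the given task.

    Rows violating the schema (negative RTs, non-positive reproductions,
    unknown choices) raise with the offending row index; an empty table
    logs a warning and returns an empty frame.
    """
    if task not in _REQUIRED:
        raise ValueError(f"unknown task {task!r}")
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = set(("subject", "viscosity") + _REQUIRED[task]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty trial table", UserWarning, stacklevel=2)
        return df
    if task == "categorization":
        bad = df.index[df["rt_s"] <= 0]
        if len(bad):
            raise ValueError(f"{path}: non-positive rt_s at row(s) {list(bad[:5])}")
        bad = df.index[~df["choice"].isin(["long", "short"])]
        if len(bad):
            raise ValueError(f"{path}: invalid choice at row(s) {list(bad[:5])}")
    else:
        bad = df.index[(df["tp_s"] <= 0) | (df["ts_s"] <= 0)]
        if len(bad):
            raise ValueError(
                f"{path}: non-positive ts_s/tp_s at row(s) {list(bad[:5])}"
            )
    return df


def load_config(path: str | Path) -> SessionConfig:
    """Load a flat YAML key-value session configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"task", "durations", "viscosities", "trials_per_cell", "n_blocks", "seed"}
    unknown = set(raw) - known
    if unknown:
        logger.warning("ignoring unknown config keys: %s", sorted(unknown))
    kwargs = {k: raw[k] for k in known & set(raw)}
    for key in ("durations", "viscosities"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    return SessionConfig(**kwargs)
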
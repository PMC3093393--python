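"""Trial-table CSV format, truth sidecars, and run configuration.

Trial tables are stored in pixels (the unit of the experiments); logs and
normalization are applied internally by the analyses.  The CSV schema is

    subject_id, trial_index, l1_px, l2_px, is_impossible, interfered, response

with flags coded 0/1 and the response coded 1 = 'first longer',
2 = 'second longer', empty = absent.  Writing then reading reproduces the
table exactly (floats are written with round-trip precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import SchemaViolationError
from .simulate import TRIAL_COLUMNS, TaskConfig

__all__ = [
    "read_trials",
    "write_trials",
    "write_truth",
    "read_truth",
    "RunConfig",
]

_REL_TOL = 1e-9  # is_impossible must agree with the lengths to this relative tolerance


def write_trials(path, table: pd.DataFrame) -> None:
    """Write a trial table as CSV (flags as 0/1, response 1/2/empty)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaViolationError(f"table missing columns: {missing}")
    out = table[TRIAL_COLUMNS].copy()
    out["is_impossible"] = out["is_impossible"].astype(bool).astype(int)
    out["interfered"] = out["interfered"].astype(bool).astype(int)
    out["response"] = out["response"].astype("Int64")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`SchemaViolationError` (naming the first offending file
    line) on missing columns, non-positive lengths, response codes outside
    {1, 2, empty}, or an ``is_impossible`` flag inconsistent with the
    lengths.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "response": "Int64"})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaViolationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return _finalize(df)

    def _line(mask) -> int:
        # +2: header line plus 1-based indexing
        return int(np.flatnonzero(mask)[0]) + 2

    l1 = df["l1_px"].to_numpy(dtype=float)
    l2 = df["l2_px"].to_numpy(dtype=float)
    bad = (l1 <= 0) | (l2 <= 0) | ~np.isfinite(l1) | ~np.isfinite(l2)
    if bad.any():
        raise SchemaViolationError(f"{path}:{_line(bad)}: non-positive or non-finite length")
    flags = df["is_impossible"].to_numpy()
    if not np.isin(flags, (0, 1, True, False)).all():
        raise SchemaViolationError(f"{path}: is_impossible must be 0/1")
    equal = np.abs(l1 - l2) <= _REL_TOL * np.abs(l1)
    mismatch = equal != flags.astype(bool)
    if mismatch.any():
        raise SchemaViolationError(
            f"{path}:{_line(mismatch)}: is_impossible flag inconsistent with lengths"
        )
    resp = df["response"]
    bad_resp = resp.notna() & ~resp.isin([1, 2])
    if bad_resp.any():
        raise SchemaViolationError(
            f"{path}:{_line(bad_resp.to_numpy())}: response must be 1, 2 or empty"
        )
    return _finalize(df)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df[TRIAL_COLUMNS].copy()
    out["trial_index"] = out["trial_index"].astype(np.int64)
    out["l1_px"] = out["l1_px"].astype(float)
    out["l2_px"] = out["l2_px"].astype(float)
    out["is_impossible"] = out["is_impossible"].astype(bool)
    out["interfered"] = out["interfered"].astype(bool)
    out["response"] = out["response"].astype("Int64")
    return out


def write_truth(path, truth: pd.DataFrame) -> None:
    """Sidecar with the true per-subject generating parameters (JSON)."""
    payload = {row["subject_id"]: {k: v for k, v in row.items() if k != "subject_id"}
               for row in truth.to_dict("records")}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    rows = [{"subject_id": k, **v} for k, v in sorted(payload.items())]
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: task, cohort, analysis and
    fit settings plus the master seed.  Serializes to/from plain JSON."""

    task: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=lambda: {"n_subjects": 9})
    analysis: dict = field(default_factory=lambda: {"n_bins": 10, "n_boot": 5000, "level": 0.95})
    fit: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    def task_config(self) -> TaskConfig:
        kwargs = dict(self.task)
        if "range_px" in kwargs:
            kwargs["range_px"] = tuple(kwargs["range_px"])
        if "deltas" in kwargs:
            kwargs["deltas"] = tuple(kwargs["deltas"])
        return TaskConfig(**kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
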
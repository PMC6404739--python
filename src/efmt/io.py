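"""CSV/JSON interchange and run manifests.

CSV dialect: UTF-8, comma-separated, mandatory header, empty fields for
missing values.  ``write_trial_csv`` / ``read_trial_csv`` round-trip the long
visit table byte-identically; schema violations are reported with row numbers.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .trial import LONG_COLUMNS, TrialDataset

__all__ = ["SchemaError", "RunManifest", "write_trial_csv", "read_trial_csv",
           "write_dataset", "read_dataset"]

_DTYPES = {"participant_id": str, "arm": str, "week": int, "hamd_total": int,
           "bdi": int, "sessions_this_week": int, "sessions_cum": int,
           "status": str, "itt": bool, "mitt": bool}


class SchemaError(ValueError):
    """Schema violation with an itemized report."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("trial CSV schema violations:\n  " + "\n  ".join(problems))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-identically (modulo timestamp)."""

    command: str
    seed: Optional[int]
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = __version__
    python_version: str = platform.python_version()
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, sort_keys=True) + "\n")


def config_hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_long(df: pd.DataFrame) -> None:
    problems: list[str] = []
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing required column: {c}" for c in missing])
    for col in ["week", "hamd_total", "sessions_this_week", "sessions_cum"]:
        bad = df.index[df[col] < 0]
        problems += [f"row {i}: negative {col}" for i in bad[:20]]
    bad_week = df.index[(df["week"] > 6)]
    problems += [f"row {i}: week out of 0..6" for i in bad_week[:20]]
    item_cols = [c for c in df.columns if c.startswith("hamd_item_")]
    sums = df[item_cols].sum(axis=1)
    bad_sum = df.index[sums != df["hamd_total"]]
    problems += [f"row {i}: Ham-D items do not sum to hamd_total" for i in bad_sum[:20]]
    for pid, g in df.groupby("participant_id"):
        g = g.sort_values("week")
        if (g["sessions_cum"].diff().dropna() < 0).any():
            problems.append(f"participant {pid}: sessions_cum decreases")
        status = list(g["status"])
        if "discontinued" in status and status.index("discontinued") != len(status) - 1:
            problems.append(f"participant {pid}: records after discontinuation")
    if problems:
        raise SchemaError(problems)


def write_trial_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_long(df)
    df.to_csv(path, index=False, lineterminator="\n")


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "arm": str, "status": str})
    validate_long(df)
    return df.astype({k: v for k, v in _DTYPES.items() if k in df.columns})


def write_dataset(dataset: TrialDataset, outdir: str | Path,
                  seed: Optional[int] = None, command: str = "simulate-trial") -> list[Path]:
    """Write trial_long.csv, participants.csv, allocation.csv (+LOCF variant
    if present) and a JSON run manifest; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "trial_long.csv"
    write_trial_csv(dataset.long, p)
    paths.append(p)
    for name, df in [("participants.csv", dataset.participants),
                     ("allocation.csv", dataset.allocation)]:
        q = outdir / name
        df.to_csv(q, index=False, lineterminator="\n")
        paths.append(q)
    if dataset.locf is not None:
        q = outdir / "trial_long_locf.csv"
        dataset.locf.to_csv(q, index=False, lineterminator="\n")
        paths.append(q)
    cfg = dataset.config.to_dict() if dataset.config is not None else {}
    manifest = RunManifest(command=command, seed=seed if seed is not None else dataset.seed,
                           config_hash=config_hash(cfg),
                           outputs=[str(x) for x in paths])
    manifest.write(outdir / "manifest.json")
    paths.append(outdir / "manifest.json")
    return paths


def read_dataset(indir: str | Path) -> TrialDataset:
    indir = Path(indir)
    long = read_trial_csv(indir / "trial_long.csv")
    participants = pd.read_csv(indir / "participants.csv")
    alloc_path = indir / "allocation.csv"
    allocation = pd.read_csv(alloc_path) if alloc_path.exists() else pd.DataFrame()
    locf_path = indir / "trial_long_locf.csv"
    locf = pd.read_csv(locf_path) if locf_path.exists() else None
    return TrialDataset(long=long, participants=participants,
                        allocation=allocation, locf=locf)
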
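"""Experiment-table schema, I/O and subsetting.

The unit of observation is one cage of infected insects from one replicate
experiment, one diet group (blood meal yes/no x sucrose concentration
high/low), observed on one day post-infection: a pair of (alive, dead)
counts plus the pooled bacterial load of the individuals sampled for
quantification on that day.

Columns of the on-disk CSV::

    replicate,day,blood,sucrose,alive,dead,load_cfu

``load_cfu`` is the pooled median colony-forming-unit count per insect; the
reader applies a configurable transform (default ``log10p1``, i.e.
``log10(CFU + 1)``) and the table remembers which transform produced its
``load`` column so it can be inverted on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VALID_DAYS",
    "LOAD_TRANSFORMS",
    "SchemaError",
    "ExperimentTable",
    "read_experiment_table",
    "write_experiment_table",
    "from_dataframe",
    "subset",
    "validate_table",
]

VALID_DAYS = (1, 3, 5)

REQUIRED_COLUMNS = ("replicate", "day", "blood", "sucrose", "alive", "dead", "load_cfu")

#: transform name -> (forward on CFU scale, inverse back to CFU)
LOAD_TRANSFORMS = {
    "log10": (lambda c: np.log10(c), lambda x: 10.0**x),
    "log10p1": (lambda c: np.log10(np.asarray(c, dtype=float) + 1.0), lambda x: 10.0**x - 1.0),
    "identity": (lambda c: np.asarray(c, dtype=float), lambda x: x),
}


class SchemaError(ValueError):
    """Input file does not match the experiment-table schema."""


@dataclass
class ExperimentTable:
    """A validated per-cage observation table.

    Attributes
    ----------
    data:
        DataFrame with columns ``replicate, day, blood, sucrose, alive,
        dead, load`` where ``load`` is on the configured transform scale.
    metadata:
        Provenance: source path (if any) and the load transform applied.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def load_transform(self) -> str:
        return self.metadata.get("load_transform", "identity")

    @property
    def days(self) -> list[int]:
        return sorted(self.data["day"].unique())

    def copy(self) -> "ExperimentTable":
        return ExperimentTable(self.data.copy(), dict(self.metadata))

    def subset(self, day: int | None = None, blood: int | None = None,
               sucrose: int | None = None) -> "ExperimentTable":
        return subset(self, day=day, blood=blood, sucrose=sucrose)

    def validate(self) -> list[str]:
        return validate_table(self)


def _check_schema(df: pd.DataFrame, strict_days: bool = True) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise SchemaError("experiment table has no rows")
    bad_days = sorted(set(df["day"].unique()) - set(VALID_DAYS))
    if strict_days and bad_days:
        raise ValueError(f"day values outside {VALID_DAYS}: {bad_days}")
    for col in ("alive", "dead"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    for col in ("blood", "sucrose"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"column {col!r} must be binary 0/1")


def from_dataframe(df: pd.DataFrame, load_transform: str = "log10p1",
                   source: str | None = None) -> ExperimentTable:
    """Build a validated :class:`ExperimentTable` from a raw-CFU dataframe."""
    if load_transform not in LOAD_TRANSFORMS:
        raise ValueError(f"unknown load transform {load_transform!r}; "
                         f"choose from {sorted(LOAD_TRANSFORMS)}")
    _check_schema(df)
    fwd, _ = LOAD_TRANSFORMS[load_transform]
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["load"] = fwd(out.pop("load_cfu").to_numpy(dtype=float))
    for col in ("replicate", "day", "blood", "sucrose", "alive", "dead"):
        out[col] = out[col].astype(int)
    meta = {"load_transform": load_transform}
    if source is not None:
        meta["source"] = source
    return ExperimentTable(out.reset_index(drop=True), meta)


def read_experiment_table(path: str | Path, load_transform: str = "log10p1") -> ExperimentTable:
    """Read a per-cage CSV and apply the load transform.

    Raises
    ------
    SchemaError
        If required columns are absent or the file is empty.
    ValueError
        On invalid day levels, negative counts, or non-binary treatments.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    return from_dataframe(df, load_transform=load_transform, source=str(path))


def write_experiment_table(table: ExperimentTable, path: str | Path) -> None:
    """Write a table back to CSV on the raw CFU scale (transform inverted)."""
    _, inv = LOAD_TRANSFORMS[table.load_transform]
    df = table.data.copy()
    df["load_cfu"] = inv(df.pop("load").to_numpy(dtype=float))
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def subset(table: ExperimentTable, day: int | None = None, blood: int | None = None,
           sucrose: int | None = None) -> ExperimentTable:
    """Filter rows by day and/or treatment status, preserving order and metadata.

    An absent filter level yields an empty table (with an ``empty_subset``
    note in its metadata), not an error: day-specific analyses skip such
    subsets with a warning instead of aborting the run.
    """
    mask = pd.Series(True, index=table.data.index)
    for col, value in (("day", day), ("blood", blood), ("sucrose", sucrose)):
        if value is not None:
            mask &= table.data[col] == value
    data = table.data.loc[mask].reset_index(drop=True)
    meta = dict(table.metadata)
    if data.empty:
        meta["empty_subset"] = f"day={day}, blood={blood}, sucrose={sucrose}"
    return ExperimentTable(data, meta)


def validate_table(table: ExperimentTable) -> list[str]:
    """Diagnostics for the table invariants; empty list iff all hold."""
    diags: list[str] = []
    df = table.data
    dupes = df.duplicated(subset=["replicate", "day", "blood", "sucrose"], keep=False)
    if dupes.any():
        keys = df.loc[dupes, ["replicate", "day", "blood", "sucrose"]]
        for key in sorted(set(map(tuple, keys.to_numpy().tolist()))):
            diags.append(f"duplicate (replicate, day, blood, sucrose) key: {key}")
    zero = df["alive"] + df["dead"] == 0
    for idx in df.index[zero]:
        diags.append(f"row {idx}: alive + dead == 0 (no survival denominator)")
    nonfinite = ~np.isfinite(df["load"])
    for idx in df.index[nonfinite]:
        diags.append(f"row {idx}: non-finite load {df.loc[idx, 'load']}")
    bad_day = ~df["day"].isin(VALID_DAYS)
    for idx in df.index[bad_day]:
        diags.append(f"row {idx}: day {df.loc[idx, 'day']} outside {VALID_DAYS}")
    return diags
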
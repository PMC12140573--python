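"""Trial-table and signal-container input/output.

The central tabular object is the *trial table*: one row per trial with four
metadata columns (subject, category, error, duration) followed by the 48
element columns in the frozen region-major order.  It travels as a plain
pandas DataFrame; :func:`validate_table` enforces the schema at module
boundaries.

Raw per-trial, per-region time courses are stored in an HDF5 container with
one group per trial (datasets per region; onset/offset/metadata as
attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import CATEGORIES, META_COLUMNS, REGIONS, element_columns

TABLE_COLUMNS: tuple[str, ...] = tuple(META_COLUMNS) + tuple(element_columns())


def validate_table(table: pd.DataFrame, require_behavior: bool = True) -> pd.DataFrame:
    """Check a trial table's schema and values; return it unchanged.

    Raises ``ValueError`` naming the first offending column.  Element values
    must be finite; categories must come from the six known labels;
    durations must be positive.
    """
    for col in TABLE_COLUMNS:
        if col in ("error", "duration") and not require_behavior:
            continue
        if col not in table.columns:
            raise ValueError(f"trial table is missing column {col!r}")
    bad = set(table["category"].unique()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown trial categories {sorted(bad)}")
    elems = table[element_columns()].to_numpy(dtype=float)
    if not np.isfinite(elems).all():
        j = int(np.argwhere(~np.isfinite(elems))[0, 1])
        raise ValueError(f"non-finite element values in column {element_columns()[j]!r}")
    if require_behavior and (table["duration"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("column 'duration' contains non-positive values")
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_table(table)
    table.to_csv(path, index=False, columns=list(TABLE_COLUMNS))


def read_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_table(table)


@dataclass
class TrialSignals:
    """Raw time courses for one trial: one row per region, fs-sampled."""

    trial_id: int
    subject: str
    category: str
    onset: float
    offset: float
    fs: float
    times: np.ndarray
    data: np.ndarray  # regions x samples
    error: float = np.nan
    duration: float = np.nan

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape != (len(REGIONS), self.times.size):
            raise ValueError(
                f"data must be {len(REGIONS)} x {self.times.size}, got {self.data.shape}"
            )


@dataclass
class SignalSet:
    """A collection of per-trial signals plus the generating portrait table."""

    trials: list[TrialSignals] = field(default_factory=list)
    fs: float = 256.0
    table: pd.DataFrame | None = None


def save_signals(signals: SignalSet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["fs"] = signals.fs
        for tr in signals.trials:
            g = h5.create_group(f"trial_{tr.trial_id:06d}")
            g.create_dataset("data", data=tr.data)
            g.create_dataset("times", data=tr.times)
            g.attrs.update(
                trial_id=tr.trial_id,
                subject=tr.subject,
                category=tr.category,
                onset=tr.onset,
                offset=tr.offset,
                fs=tr.fs,
                error=tr.error,
                duration=tr.duration,
            )
        if signals.table is not None:
            g = h5.create_group("table")
            g.create_dataset(
                "csv",
                data=np.bytes_(signals.table.to_csv(index=False).encode()),
            )


def load_signals(path: str | Path) -> SignalSet:
    import h5py
    import io as _io

    out = SignalSet(trials=[])
    with h5py.File(path, "r") as h5:
        out.fs = float(h5.attrs["fs"])
        for key in sorted(h5.keys()):
            if not key.startswith("trial_"):
                continue
            g = h5[key]
            out.trials.append(
                TrialSignals(
                    trial_id=int(g.attrs["trial_id"]),
                    subject=str(g.attrs["subject"]),
                    category=str(g.attrs["category"]),
                    onset=float(g.attrs["onset"]),
                    offset=float(g.attrs["offset"]),
                    fs=float(g.attrs["fs"]),
                    times=g["times"][()],
                    data=g["data"][()],
                    error=float(g.attrs["error"]),
                    duration=float(g.attrs["duration"]),
                )
            )
        if "table" in h5:
            csv = bytes(h5["table/csv"][()]).decode()
            out.table = pd.read_csv(_io.StringIO(csv))
    return out
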
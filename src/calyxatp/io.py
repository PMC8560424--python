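"""Delimited-text I/O for stimulus-aligned EPSC amplitude tables.

The on-disk schema is a plain tab- or comma-delimited table with one row
per stimulus and columns ``cell_id, condition, run_index, train_role,
stim_index, time_s, amplitude``.  Rows group into one
:class:`~calyxatp.trains.EpscTrain` per unique (cell_id, condition,
run_index, train_role); the stimulation frequency is inferred from the
median inter-stimulus interval.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .trains import EpscTrain

__all__ = ["REQUIRED_COLUMNS", "read_amplitude_table", "write_amplitude_table"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_id", "condition", "run_index", "train_role",
                    "stim_index", "time_s", "amplitude")

_GROUP_KEYS = ["cell_id", "condition", "run_index", "train_role"]


class AmplitudeTableError(ValueError):
    """Raised for schema or content problems in an amplitude table."""


def read_amplitude_table(path) -> list[EpscTrain]:
    """Parse an amplitude table into typed trains.

    Raises :class:`AmplitudeTableError` naming the offending column or the
    1-based data row for missing columns, non-numeric fields, or stimulus
    times that are not strictly ascending within a train.  An empty or
    header-only file yields an empty list with a warning.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("amplitude table %s is empty", path)
        return []
    except csv.Error:
        # delimiter sniffing fails on header-only files; tabs, then commas
        try:
            df = pd.read_csv(path, sep="\t")
            if len(df.columns) == 1:
                df = pd.read_csv(path, sep=",")
        except pd.errors.EmptyDataError:
            return []
    if df.empty:
        logger.warning("amplitude table %s has a header but no rows", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AmplitudeTableError(
            f"{path}: missing required columns {missing}; "
            f"found {list(df.columns)}")
    for col in ("stim_index", "time_s", "amplitude", "run_index"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise AmplitudeTableError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}")
        df[col] = coerced

    trains: list[EpscTrain] = []
    for (cell, cond, run, role), grp in df.groupby(_GROUP_KEYS, sort=False):
        grp = grp.sort_values("stim_index")
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            bad_pos = int(np.flatnonzero(np.diff(t) <= 0)[0])
            line = int(grp.index[bad_pos + 1]) + 2
            raise AmplitudeTableError(
                f"{path}: stimulus times not strictly ascending for "
                f"cell {cell!r} condition {cond!r} run {run} near line {line}")
        freq = 1.0 / float(np.median(np.diff(t))) if len(t) >= 2 else np.nan
        trains.append(EpscTrain(
            stim_times=t,
            amplitudes=grp["amplitude"].to_numpy(dtype=float),
            frequency=freq, cell_id=str(cell), condition=str(cond),
            run_index=int(run), train_role=str(role)))
    logger.info("read %d rows -> %d trains from %s", len(df), len(trains), path)
    return trains


def write_amplitude_table(trains, path, sep: str = "\t") -> None:
    """Write trains to the delimited schema (row count = total stimuli)."""
    rows = []
    for tr in trains:
        for i, (t, a) in enumerate(zip(tr.stim_times, tr.amplitudes)):
            rows.append((tr.cell_id, tr.condition, tr.run_index,
                         tr.train_role, i, t, a))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, sep=sep, index=False)
    logger.info("wrote %d rows to %s", len(df), path)
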
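"""Reading raw vitals and grouping them into 10-minute windows.

The analysis unit is a non-overlapping 10-minute window of 0.5 Hz samples —
exactly 300 value slots on a fixed 2-second grid anchored at the cohort
epoch. Windows with any empty slot are retained but flagged incomplete, and
excluded later at the feature-filtering stage; day boundaries are fixed
86,400 s blocks from the epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import (DAY_S, SAMPLE_INTERVAL_S, WINDOW_LEN, WINDOW_S,
                               VitalSeries)

log = logging.getLogger(__name__)

VITALS_COLUMNS = ["patient_id", "timestamp_s", "signal", "value"]


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass
class WindowSample:
    """One 10-minute, 300-slot segment keyed by patient and day.

    ``values`` always has length 300; empty slots are NaN and make the
    window incomplete.
    """

    patient_id: str
    signal: str
    day_index: int
    window_start_s: int
    values: np.ndarray
    died_within_horizon: int | None = None
    days_until_death: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != WINDOW_LEN:
            raise ValueError(
                f"window must hold exactly {WINDOW_LEN} slots, "
                f"got {self.values.size}")
        if self.window_start_s % WINDOW_S != 0:
            raise ValueError("window_start_s must sit on the 600 s grid")

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


def read_vitals(path: str | Path) -> list[VitalSeries]:
    """Read a delimited vitals file into one series per (patient, signal).

    Unparseable values become flagged-missing (NaN) entries rather than
    being dropped; out-of-order timestamps are sorted with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "signal": str},
                     float_precision="round_trip")
    missing_cols = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        return []
    values = pd.to_numeric(df["value"], errors="coerce")
    n_flagged = int(values.isna().sum() - df["value"].isna().sum())
    if n_flagged:
        log.warning("%s: %d unparseable values flagged missing", path, n_flagged)
    df = df.assign(value=values)

    series = []
    for (pid, sig), grp in df.groupby(["patient_id", "signal"], sort=True):
        ts = grp["timestamp_s"].to_numpy(dtype=np.int64)
        vals = grp["value"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            log.warning("series (%s, %s): unsorted timestamps, sorting", pid, sig)
            order = np.argsort(ts, kind="stable")
            ts, vals = ts[order], vals[order]
        series.append(VitalSeries(str(pid), str(sig), ts, vals))
    return series


def make_windows(
    series: VitalSeries,
    day_length_s: int = DAY_S,
    window_s: int = WINDOW_S,
) -> list[WindowSample]:
    """Partition a series into non-overlapping fixed-grid windows.

    The grid starts at the cohort epoch (t = 0); each window covers
    ``window_s`` seconds = ``window_s / 2`` slots. Timestamps off the 2 s
    grid snap to the nearest slot; collisions keep the last value (logged).
    Every sample lands in exactly one window.
    """
    if window_s % SAMPLE_INTERVAL_S != 0:
        raise ValueError("window_s must be divisible by the 2 s interval")
    slots_per_window = window_s // SAMPLE_INTERVAL_S
    ts = series.timestamps
    if ts.size == 0:
        return []
    slot = np.rint(ts / SAMPLE_INTERVAL_S).astype(np.int64)
    values = series.values
    if np.any(np.diff(slot) < 0):          # timestamps sorted, slots may tie
        order = np.argsort(slot, kind="stable")
        slot, values = slot[order], values[order]
    widx = slot // slots_per_window
    within = slot % slots_per_window

    n_collisions = int(np.count_nonzero(np.diff(slot) == 0))
    if n_collisions:
        log.warning("series (%s, %s): %d grid collisions, keeping last value",
                    series.patient_id, series.signal, n_collisions)

    new_w = np.empty(widx.size, dtype=bool)
    new_w[0] = True
    np.not_equal(widx[1:], widx[:-1], out=new_w[1:])
    uniq_w = widx[new_w]
    inverse = np.cumsum(new_w) - 1
    buf = np.full((uniq_w.size, slots_per_window), np.nan)
    buf[inverse, within] = values          # later rows overwrite (keep last)

    out = []
    for i, w in enumerate(uniq_w):
        start = int(w) * window_s
        out.append(WindowSample(
            patient_id=series.patient_id,
            signal=series.signal,
            day_index=start // day_length_s,
            window_start_s=start,
            values=buf[i],
        ))
    return out


def assign_labels(
    windows: Iterable[WindowSample],
    outcomes: pd.DataFrame,
    horizon_days: int = 7,
) -> list[WindowSample]:
    """Attach the 7-day mortality label to each window (in place).

    ``died_within_horizon`` is 1 iff the patient dies and
    ``death_day - window_day`` falls in [0, horizon_days).
    ``days_until_death`` is measured in days from the window start to the
    end of the death day (death is localised to the end of ``death_day``),
    and left None for survivors.
    """
    info = {
        str(r.patient_id): (int(r.last_day),
                            int(r.death_day) if bool(r.died) else None)
        for r in outcomes.itertuples()
    }
    out = []
    for w in windows:
        if w.patient_id not in info:
            raise ValueError(f"outcomes table does not cover {w.patient_id}")
        last_day, death_day = info[w.patient_id]
        if w.day_index > last_day:
            raise ValueError(
                f"window day {w.day_index} after last_day {last_day} "
                f"for {w.patient_id}")
        if death_day is not None:
            delta_days = death_day - w.day_index
            w.died_within_horizon = int(0 <= delta_days < horizon_days)
            death_time_s = (death_day + 1) * DAY_S
            w.days_until_death = (death_time_s - w.window_start_s) / DAY_S
        else:
            w.died_within_horizon = 0
            w.days_until_death = None
        out.append(w)
    return out


def windows_to_frame(windows: Sequence[WindowSample]) -> pd.DataFrame:
    """Tabular view of windows (one row per window, v000..v299 columns)."""
    cols = [f"v{i:03d}" for i in range(WINDOW_LEN)]
    meta = pd.DataFrame({
        "patient_id": [w.patient_id for w in windows],
        "signal": [w.signal for w in windows],
        "day_index": [w.day_index for w in windows],
        "window_start_s": [w.window_start_s for w in windows],
    })
    vals = pd.DataFrame(
        np.vstack([w.values for w in windows]) if windows
        else np.empty((0, WINDOW_LEN)),
        columns=cols)
    return pd.concat([meta, vals], axis=1)
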
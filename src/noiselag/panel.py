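"""Space-time panel construction from timestamped call events.

Raw call events (unit, date, hour) are disaggregated onto the complete grid
of ``unit x study day x period`` cells, where each day splits into a *day*
session (05:00-21:59) and a *night* session (22:00-04:59, assigned to the
calendar date on which each call occurs).  Cell counts are dichotomized into
the binary response ``noisebin`` and six spatio-temporal lag predictors:

========== ========================================================
noisebin1  any call in the same unit/period one week earlier
noisebin2  same, two weeks earlier
noisebin11 any call among first-order neighbors one week earlier
noisebin12 any call among second-order neighbors one week earlier
noisebin21 any call among first-order neighbors two weeks earlier
noisebin22 any call among second-order neighbors two weeks earlier
========== ========================================================

Lags are period-matched (a night cell looks back at night cells).  Cells in
the first 14 study days have undefined two-week (and, for the first 7, also
one-week) lags; :func:`trim_for_lags` drops them, leaving ``U x (D-14) x 2``
records with every lag defined.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeGraph, NeighborOrders

__all__ = [
    "DAY_HOURS",
    "NIGHT_HOURS",
    "PERIODS",
    "LAG_COLUMNS",
    "CallPanel",
    "assign_period",
    "aggregate_counts",
    "add_lags",
    "trim_for_lags",
    "read_events_csv",
    "write_events_csv",
    "write_panel_csv",
    "read_panel_csv",
]

DAY_HOURS: tuple[int, ...] = tuple(range(5, 22))
NIGHT_HOURS: tuple[int, ...] = (22, 23, 0, 1, 2, 3, 4)
PERIODS: tuple[str, str] = ("day", "night")
LAG_COLUMNS: tuple[str, ...] = (
    "noisebin1",
    "noisebin2",
    "noisebin11",
    "noisebin12",
    "noisebin21",
    "noisebin22",
)
#: columns of the exported panel, keys first then the variables in their
#: conventional order (calendar terms live on `date`/`period`)
PANEL_COLUMNS: tuple[str, ...] = (
    "unit_id",
    "date_index",
    "date",
    "period",
    "noise",
    "noisebin",
) + LAG_COLUMNS


def assign_period(hour: int) -> str:
    """Map an hour of day to its session: day (5-21) or night (22-4)."""
    hour = int(hour)
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in [0, 23], got {hour}")
    return "day" if 5 <= hour <= 21 else "night"


@dataclass(frozen=True)
class CallPanel:
    """Complete call-count grid: ``counts[u, d, p]`` over units x days x periods.

    ``d`` is the zero-based study-day index (day index 1..D externally) and
    ``p`` indexes :data:`PERIODS`.
    """

    unit_ids: tuple[str, ...]
    start_date: _dt.date
    counts: np.ndarray  # (U, D, 2) int64

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.counts.shape))

    def occurrence(self) -> np.ndarray:
        """Binary occurrence grid (noisebin) of the same shape as counts."""
        return (self.counts > 0).astype(np.int64)


def aggregate_counts(
    events: pd.DataFrame,
    lattice: LatticeGraph,
    start_date: _dt.date,
    n_days: int,
) -> CallPanel:
    """Disaggregate events onto the complete (unit, day, period) grid.

    Every cell of the grid is present (zero where no call happened) and the
    grand total of counts equals the number of events.

    Parameters
    ----------
    events
        DataFrame with columns ``unit_id``, ``date`` (ISO date or datetime)
        and ``hour``; may be empty.
    lattice
        Supplies the unit universe; events in unknown units are an error.
    start_date, n_days
        The study window; events outside it are an error (the message lists
        the offending row positions).
    """
    if isinstance(start_date, str):
        start_date = _dt.date.fromisoformat(start_date)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    unit_index = {u: k for k, u in enumerate(lattice.unit_ids)}
    counts = np.zeros((len(unit_index), n_days, 2), dtype=np.int64)
    if len(events):
        missing = ~events["unit_id"].isin(unit_index)
        if missing.any():
            bad = sorted(events.loc[missing, "unit_id"].unique())
            raise ValueError(f"events reference unknown units: {bad}")
        hours = events["hour"].to_numpy()
        if ((hours < 0) | (hours > 23)).any():
            raise ValueError("event hours must be in [0, 23]")
        dates = pd.to_datetime(events["date"]).dt.normalize()
        day_idx = (dates - pd.Timestamp(start_date)).dt.days.to_numpy()
        outside = (day_idx < 0) | (day_idx >= n_days)
        if outside.any():
            rows = np.flatnonzero(outside)
            head = ", ".join(map(str, rows[:20]))
            more = "" if len(rows) <= 20 else f" (+{len(rows) - 20} more)"
            raise ValueError(
                f"{len(rows)} events fall outside the study window "
                f"[{start_date}, +{n_days}d); offending rows: {head}{more}"
            )
        u_idx = events["unit_id"].map(unit_index).to_numpy()
        p_idx = np.where((hours >= 5) & (hours <= 21), 0, 1)
        np.add.at(counts, (u_idx, day_idx, p_idx), 1)
    return CallPanel(unit_ids=lattice.unit_ids, start_date=start_date, counts=counts)


def _shift_weeks(arr: np.ndarray, days: int) -> np.ndarray:
    """Lag an (U, D, 2) array by `days` along the day axis; NaN before window."""
    out = np.full(arr.shape, np.nan)
    if days < arr.shape[1]:
        out[:, days:, :] = arr[:, : arr.shape[1] - days, :]
    return out


def add_lags(panel: CallPanel, orders: NeighborOrders) -> pd.DataFrame:
    """Build the full record table with response and lag predictors.

    One row per (unit, date, period) cell, ordered unit-major.  Lag columns
    are floats taking values 0/1 when defined and NaN for cells whose lagged
    date precedes the study window.  Neighbor aggregates are unweighted sums
    of neighbor counts, dichotomized afterwards (after dichotomization the
    row-standardized weights cannot change the indicator).
    """
    counts = panel.counts.astype(float)
    U, D, _ = counts.shape
    idx = {u: k for k, u in enumerate(panel.unit_ids)}

    def order_matrix(mapping) -> np.ndarray:
        mat = np.zeros((U, U))
        for i, neigh in mapping.items():
            for j in neigh:
                mat[idx[i], idx[j]] = 1.0
        return mat

    a1 = order_matrix(orders.order1)
    a2 = order_matrix(orders.order2)
    n1 = (a1 @ counts.reshape(U, -1)).reshape(U, D, 2)
    n2 = (a2 @ counts.reshape(U, -1)).reshape(U, D, 2)

    def lag_bin(arr: np.ndarray, days: int) -> np.ndarray:
        s = _shift_weeks(arr, days)
        return np.where(np.isnan(s), np.nan, (s > 0).astype(float))

    lag = {
        "noisebin1": lag_bin(counts, 7),
        "noisebin2": lag_bin(counts, 14),
        "noisebin11": lag_bin(n1, 7),
        "noisebin12": lag_bin(n2, 7),
        "noisebin21": lag_bin(n1, 14),
        "noisebin22": lag_bin(n2, 14),
    }

    date_index = np.tile(np.repeat(np.arange(1, D + 1), 2), U)
    dates = np.datetime64(panel.start_date) + (date_index - 1).astype("timedelta64[D]")
    frame = pd.DataFrame(
        {
            "unit_id": np.repeat(list(panel.unit_ids), D * 2),
            "date_index": date_index,
            "date": dates,
            "period": np.tile(list(PERIODS), U * D),
            "noise": panel.counts.reshape(-1),
            "noisebin": (panel.counts.reshape(-1) > 0).astype(np.int64),
        }
    )
    for name, arr in lag.items():
        frame[name] = arr.reshape(-1)
    return frame


def trim_for_lags(panel_df: pd.DataFrame) -> pd.DataFrame:
    """Drop the first 14 study days, whose two-week lags are undefined."""
    out = panel_df[panel_df["date_index"] > 14].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def read_events_csv(path) -> pd.DataFrame:
    """Read a call-event CSV with columns ``unit_id,date,hour``."""
    df = pd.read_csv(path, dtype={"unit_id": str})
    required = {"unit_id", "date", "hour"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df["hour"] = df["hour"].astype(int)
    return df


def write_events_csv(events: pd.DataFrame, path) -> None:
    out = events[["unit_id", "date", "hour"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_panel_csv(panel_df: pd.DataFrame, path) -> None:
    out = panel_df[list(PANEL_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str}, parse_dates=["date"])
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing panel columns {sorted(missing)}")
    return df
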
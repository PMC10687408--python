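"""24-hour daily milk yields from robot-visit records.

Automatic milking systems (AMS) record one milk weight per robot visit, at
irregular intervals and 2–4 visits per day.  Following the ICAR-style
procedure for AMS herds, every visit gets a 24-h yield estimated from a
trailing window of milkings, and the 24-h yield of the *last* visit of a
calendar day becomes that day's daily milk yield.

The 24-h yield here is a rate estimate: the milk harvested in the window
divided by the window's time span, scaled to 24 hours.  The yield of a
visit is the milk accumulated since the *previous* visit, so for a visit
``v`` the window uses the yields of up to 12 visits ending at ``v`` that
each have a recorded predecessor; the time span runs from the predecessor
of the window's first visit to ``v``.  A lactation's very first visit has
no predecessor and therefore anchors the first interval without
contributing yield.  Early in lactation, when fewer than 12 usable
milkings exist, all available ones are used and the count is flagged in
``n_visits_used``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "VISIT_COLUMNS",
    "DAILY_COLUMNS",
    "twenty_four_hour_yield",
    "daily_from_visits",
    "daily_table",
    "read_visits",
    "write_daily",
]

logger = logging.getLogger(__name__)

#: Schema of the visit-level input table.
VISIT_COLUMNS = [
    "herd_id",
    "cow_id",
    "parity",
    "birth_date",
    "calving_date",
    "visit_datetime",
    "yield_kg",
    "lactation_key",
]

#: Schema of the daily-record output table.
DAILY_COLUMNS = ["lactation_key", "dim", "date", "daily_yield_kg", "n_visits_used"]

#: Maximum number of previous milkings entering the 24-h window.
WINDOW_VISITS = 12


def twenty_four_hour_yield(times, yields, max_visits: int = WINDOW_VISITS):
    """24-h milk yield (kg) at the last visit of a trailing window.

    Parameters
    ----------
    times, yields
        The full visit history of the lactation up to and including the
        visit being evaluated, in time order.  ``times`` may be datetimes
        or float hours.

    Returns
    -------
    (yield_24h, n_visits_used)
        The rate-based 24-h yield and how many visit yields entered it.

    Raises
    ------
    ValueError
        If fewer than two visits are available (a visit with no
        predecessor has no defined milking interval) or the window has
        zero time span.
    """
    t = _to_hours(times)
    y = np.asarray(yields, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("a 24-h yield needs at least 2 visits (one interval)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("visits must be strictly ordered in time")
    k = n - 1
    m = min(max_visits, k)  # usable yields: visits k-m+1..k, anchored at k-m
    span_h = t[k] - t[k - m]
    if span_h <= 0:
        raise ValueError("window time span must be positive")
    total = float(np.sum(y[k - m + 1 : k + 1]))
    return total * 24.0 / span_h, m


def _to_hours(times) -> np.ndarray:
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.datetime64):
        return (arr - arr[0]) / np.timedelta64(1, "h") if arr.size else arr.astype(float)
    return arr.astype(float)


def daily_from_visits(visits: pd.DataFrame, calving_date) -> pd.DataFrame:
    """Daily records for one lactation: one row per calendar day with visits.

    ``visits`` must hold one lactation's rows, time-sorted, with columns
    ``visit_datetime`` and ``yield_kg`` (plus ``lactation_key``).  DIM is
    whole days since calving (calving day = DIM 0, first full day = DIM 1);
    DIM-0 records are not emitted.  Days whose last visit is the
    lactation's first visit are skipped with a warning.  Visits dated
    before calving raise an error listing the offending rows.
    """
    visits = visits.sort_values("visit_datetime", kind="stable")
    calving = pd.Timestamp(calving_date)
    dates = visits["visit_datetime"].dt.normalize()
    bad = visits.index[dates < calving.normalize()]
    if len(bad):
        raise ValueError(f"visits before calving date at rows {list(bad)}")
    key = visits["lactation_key"].iloc[0] if "lactation_key" in visits else None

    t_h = (
        visits["visit_datetime"] - visits["visit_datetime"].iloc[0]
    ).dt.total_seconds().to_numpy() / 3600.0
    y = visits["yield_kg"].to_numpy(dtype=float)
    n = len(visits)

    rows = []
    # last visit index of each calendar day
    day_last = (
        pd.Series(np.arange(n), index=dates.to_numpy()).groupby(level=0).max()
    )
    for day, k in day_last.items():
        dim = (pd.Timestamp(day) - calving.normalize()).days
        if dim < 1:
            continue
        if k == 0:
            logger.warning(
                "lactation %s: single visit with no predecessor on %s; day skipped",
                key,
                day,
            )
            continue
        y24, m = twenty_four_hour_yield(t_h[: k + 1], y[: k + 1])
        rows.append((key, dim, pd.Timestamp(day), y24, m))
    return pd.DataFrame(rows, columns=DAILY_COLUMNS)


def daily_table(visits: pd.DataFrame, lactations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised daily-record table for a whole visit-level dataset.

    ``lactations`` supplies ``lactation_key`` and ``calving_date``.
    Implements the same trailing-window rule as :func:`daily_from_visits`
    but in one pass over the sorted table, which matters at cohort scale.
    """
    v = visits.drop(columns=["calving_date"], errors="ignore").merge(
        lactations[["lactation_key", "calving_date"]], on="lactation_key", how="left"
    )
    v = v.sort_values(["lactation_key", "visit_datetime"], kind="stable").reset_index(
        drop=True
    )
    if (v["visit_datetime"].dt.normalize() < v["calving_date"]).any():
        nbad = int((v["visit_datetime"].dt.normalize() < v["calving_date"]).sum())
        raise ValueError(f"{nbad} visits dated before their calving date")

    t_h = v["visit_datetime"].astype("int64").to_numpy() / 3.6e12  # epoch hours
    y = v["yield_kg"].to_numpy(dtype=float)
    pos = v.groupby("lactation_key", sort=False).cumcount().to_numpy()

    m = np.minimum(WINDOW_VISITS, pos)  # usable yields per visit
    idx = np.arange(len(v))
    cs = np.concatenate([[0.0], np.cumsum(y)])
    wsum = cs[idx + 1] - cs[idx + 1 - m]
    span = t_h - t_h[idx - m]
    with np.errstate(divide="ignore", invalid="ignore"):
        y24 = np.where(m > 0, wsum * 24.0 / span, np.nan)

    v["_y24"] = y24
    v["_m"] = m
    v["date"] = v["visit_datetime"].dt.normalize()
    v["dim"] = (v["date"] - v["calving_date"]).dt.days
    # last visit per lactation-day
    last = v.drop_duplicates(["lactation_key", "date"], keep="last")
    skipped = int((last["_m"] == 0).sum())
    if skipped:
        logger.warning(
            "%d days whose last visit had no predecessor were skipped", skipped
        )
    out = last[(last["_m"] > 0) & (last["dim"] >= 1)]
    out = out[["lactation_key", "dim", "date", "_y24", "_m"]].rename(
        columns={"_y24": "daily_yield_kg", "_m": "n_visits_used"}
    )
    return out.reset_index(drop=True)


def read_visits(path) -> pd.DataFrame:
    """Read a visit-level CSV and derive ``lactation_key`` if absent."""
    df = pd.read_csv(
        path, parse_dates=["birth_date", "calving_date", "visit_datetime"]
    )
    if "lactation_key" not in df.columns:
        df["lactation_key"] = (
            df["cow_id"].astype(str) + "_p" + df["parity"].astype("Int64").astype(str)
        )
    return df


def write_daily(daily: pd.DataFrame, path) -> None:
    daily.to_csv(path, index=False)
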
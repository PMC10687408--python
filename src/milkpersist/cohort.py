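"""Cohort construction: editing cascade, breeding status, herd-year
covariates and the insemination-moment model datasets.

AMS herd data are noisy: parities go unrecorded, heifers calve at
implausible ages, lactations run extremely long, and curve fits misbehave
(negative decay, huge RMSE, extreme parameters).  The cascade below removes
these in a fixed order, logging the count excluded at every step so the
surviving cohort is auditable.

Lactation-level filters (before any fitting):
  1. missing parity;
  2. age at calving outside the (1%, 99%) percentiles *within parity*;
  3. lactation length above the 99% percentile.

Post-fit filters (on the per-record fitted curves):
  1. lactations ending before DIM 305 (no 305-day target exists);
  2. records with negative decay;
  3. records with fit RMSE above the 95% percentile;
  4. records with magnitude, time-to-peak or decay outside (1%, 99%);
  5. lactations lacking a curve at DIM 305 and at DIM 304 (304 is the only
     accepted substitute for a missing 305 record).

Percentiles are linear-interpolation quantiles and all thresholds are
strict exceedances, so degenerate (all-identical) distributions drop
nothing.

Breeding status per daily record: conception is back-calculated as the next
calving date minus a 282-day gestation; a record is ``Bred`` when that
conception date is strictly earlier than the record date, ``Never`` when no
next calving exists, and ``Open`` otherwise (a record exactly on the
conception date is still Open).  Only Open records can enter the
insemination-moment datasets — those are the cows whose insemination
decision is still to be made.

Herd covariates: individual lactations are aggregated to the calendar year
in which the lactation ended.  Herd-level curve characteristics (HLCC) are
means per herd x year x parity group; the herd 305-day yield (HM305) is a
mean per herd x year.  A model row may only use summaries from the year
*before* its own lactation's end year — herd information that would have
been available at decision time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .milkbot import LactationCurveCharacteristics, m305

__all__ = [
    "SEASON_OF_MONTH",
    "FALLBACK_BOUNDS",
    "GESTATION_DAYS",
    "DAYS_PER_MONTH",
    "calving_season",
    "build_lactation_table",
    "lactation_level_filters",
    "post_fit_filters",
    "assign_breeding_status",
    "final_curve_table",
    "herd_year_aggregate",
    "build_insemination_dataset",
]

logger = logging.getLogger(__name__)

#: Calving month -> season (3-5 Spring, 6-8 Summer, 9-11 Autumn, 12-2 Winter).
SEASON_OF_MONTH = {
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
    12: "Winter", 1: "Winter", 2: "Winter",
}

#: Earliest acceptable fallback day for each insemination moment.
FALLBACK_BOUNDS = {50: 48, 75: 74, 100: 98, 125: 122}

#: Gestation length used to back-calculate conception dates.
GESTATION_DAYS = 282

#: Mean Gregorian month length; converts age in days to age in months.
DAYS_PER_MONTH = 30.4375

SCHEMA_VERSION = 1


def calving_season(month: int) -> str:
    return SEASON_OF_MONTH[int(month)]


def _log_entry(step: str, n_excluded: int, n_remaining: int) -> dict:
    return {"step": step, "n_excluded": int(n_excluded), "n_remaining": int(n_remaining)}


def build_lactation_table(cows: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Lactation-level table with derived fields.

    ``cows`` has one row per lactation (lactation_key, cow_id, herd_id,
    parity, birth_date, calving_date, next_calving_date); ``daily`` supplies
    lactation length (DIM of the last daily record) and the end year.
    """
    lact = cows.copy()
    lact["parity_group"] = np.where(lact["parity"] == 1, "primiparous", "multiparous")
    lact.loc[lact["parity"].isna(), "parity_group"] = np.nan
    lact["age_days"] = (lact["calving_date"] - lact["birth_date"]).dt.days
    lact["calving_season"] = lact["calving_date"].dt.month.map(SEASON_OF_MONTH)
    ends = daily.groupby("lactation_key")["dim"].max().rename("lactation_length")
    lact = lact.merge(ends, on="lactation_key", how="left")
    end_date = lact["calving_date"] + pd.to_timedelta(
        lact["lactation_length"].fillna(0), unit="D"
    )
    lact["end_year"] = end_date.dt.year
    lact["schema_version"] = SCHEMA_VERSION
    return lact


def lactation_level_filters(
    lactations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the pre-fit lactation filters in order; return (kept, log)."""
    log = []
    df = lactations

    keep = df["parity"].notna()
    log.append(_log_entry("missing_parity", (~keep).sum(), keep.sum()))
    df = df[keep]

    if len(df):
        drop = pd.Series(False, index=df.index)
        for _, grp in df.groupby("parity"):
            q1, q99 = np.quantile(grp["age_days"], [0.01, 0.99])
            drop.loc[grp.index] = (grp["age_days"] < q1) | (grp["age_days"] > q99)
        log.append(_log_entry("extreme_age_within_parity", drop.sum(), (~drop).sum()))
        df = df[~drop]
    else:
        log.append(_log_entry("extreme_age_within_parity", 0, 0))

    if len(df):
        q99 = np.quantile(df["lactation_length"].dropna(), 0.99) if df[
            "lactation_length"
        ].notna().any() else np.inf
        drop = df["lactation_length"] > q99
        log.append(_log_entry("extreme_lactation_length", drop.sum(), (~drop).sum()))
        df = df[~drop]
    else:
        log.append(_log_entry("extreme_lactation_length", 0, 0))

    return df.copy(), pd.DataFrame(log)


def post_fit_filters(
    fits: pd.DataFrame, lactations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the post-fit record filters in order; return (kept, log).

    ``fits`` is the fitted-curve table (one row per lactation x as-of DIM);
    ``lactations`` supplies ``lactation_length``.
    """
    log = []
    df = fits.merge(
        lactations[["lactation_key", "lactation_length"]], on="lactation_key", how="left"
    )

    keep = df["lactation_length"] >= 305
    log.append(_log_entry("lactation_ends_before_305", (~keep).sum(), keep.sum()))
    df = df[keep]

    keep = df["decay"] >= 0
    log.append(_log_entry("negative_decay", (~keep).sum(), keep.sum()))
    df = df[keep]

    if len(df):
        q95 = np.quantile(df["fit_rmse"], 0.95)
        keep = ~(df["fit_rmse"] > q95)
        log.append(_log_entry("rmse_above_95pct", (~keep).sum(), keep.sum()))
        df = df[keep]
    else:
        log.append(_log_entry("rmse_above_95pct", 0, 0))

    if len(df):
        drop = pd.Series(False, index=df.index)
        for col in ("magnitude", "ramp", "decay"):
            q1, q99 = np.quantile(df[col], [0.01, 0.99])
            drop |= (df[col] < q1) | (df[col] > q99)
        log.append(_log_entry("extreme_lcc", drop.sum(), (~drop).sum()))
        df = df[~drop]
    else:
        log.append(_log_entry("extreme_lcc", 0, 0))

    has_target = df[df["as_of_dim"].isin([304, 305])]["lactation_key"].unique()
    keep = df["lactation_key"].isin(has_target)
    log.append(_log_entry("no_curve_at_305_or_304", (~keep).sum(), keep.sum()))
    df = df[keep]

    return df.drop(columns=["lactation_length"]).copy(), pd.DataFrame(log)


def assign_breeding_status(
    daily: pd.DataFrame, lactations: pd.DataFrame
) -> pd.DataFrame:
    """Attach a ``breeding_status`` column (Open / Bred / Never) to daily records."""
    df = daily.merge(
        lactations[["lactation_key", "calving_date", "next_calving_date"]],
        on="lactation_key",
        how="left",
    )
    record_date = df["calving_date"] + pd.to_timedelta(df["dim"], unit="D")
    conception = df["next_calving_date"] - pd.Timedelta(days=GESTATION_DAYS)
    status = np.where(
        df["next_calving_date"].isna(),
        "Never",
        np.where(conception < record_date, "Bred", "Open"),
    )
    out = daily.copy()
    out["breeding_status"] = status
    return out


def final_curve_table(fits: pd.DataFrame, lactations: pd.DataFrame) -> pd.DataFrame:
    """One row per lactation: the 305-day curve (DIM 304 substituting) + M305."""
    cand = fits[fits["as_of_dim"].isin([304, 305])]
    cand = cand.sort_values("as_of_dim").drop_duplicates("lactation_key", keep="last")
    cand = cand.merge(
        lactations[["lactation_key", "herd_id", "parity_group", "end_year"]],
        on="lactation_key",
        how="left",
    )
    cand["m305"] = [
        m305(LactationCurveCharacteristics(a, b, c, d))
        for a, b, c, d in cand[["magnitude", "ramp", "offset", "decay"]].to_numpy()
    ]
    return cand.reset_index(drop=True)


def herd_year_aggregate(final_curves: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(HLCC, HM305) summary tables from per-lactation final curves.

    HLCC is keyed by (herd_id, year, parity_group); HM305 by (herd_id, year)
    only.  ``year`` is the calendar year in which the lactation ended.
    """
    hlcc = (
        final_curves.groupby(["herd_id", "end_year", "parity_group"])[
            ["magnitude", "ramp", "offset", "decay"]
        ]
        .mean()
        .reset_index()
        .rename(
            columns={
                "end_year": "year",
                "magnitude": "herd_magnitude",
                "ramp": "herd_time_to_peak",
                "offset": "herd_offset",
                "decay": "herd_decay",
            }
        )
    )
    hm305 = (
        final_curves.groupby(["herd_id", "end_year"])["m305"]
        .mean()
        .reset_index()
        .rename(columns={"end_year": "year", "m305": "herd_m305"})
    )
    return hlcc, hm305


def build_insemination_dataset(
    moment: int,
    fits: pd.DataFrame,
    daily: pd.DataFrame,
    lactations: pd.DataFrame,
    hlcc: pd.DataFrame,
    hm305: pd.DataFrame,
) -> pd.DataFrame:
    """Feature/target table for one candidate insemination moment.

    For every lactation still Open at the moment, the row uses the fitted
    curve at exactly ``moment`` DIM or, failing that, the closest earlier
    fitted day no earlier than the fallback bound (48/74/98/122).  Features
    are joined from the daily record at that day, the lactation covariates,
    and the previous-calendar-year herd summaries; the target is the decay
    of the 305-day curve (DIM 304 substituting).  Rows lacking previous-year
    herd summaries are dropped.
    """
    if moment not in FALLBACK_BOUNDS:
        raise ValueError(
            f"moment must be one of {sorted(FALLBACK_BOUNDS)}, got {moment!r}"
        )
    bound = FALLBACK_BOUNDS[moment]

    window = fits[(fits["as_of_dim"] >= bound) & (fits["as_of_dim"] <= moment)]
    chosen = window.sort_values("as_of_dim").drop_duplicates(
        "lactation_key", keep="last"
    )

    final = final_curve_table(fits, lactations)
    targets = final[["lactation_key", "decay", "m305"]].rename(
        columns={"decay": "decay_305", "m305": "m305_target"}
    )

    if "breeding_status" not in daily.columns:
        daily = assign_breeding_status(daily, lactations)
    day_info = daily[["lactation_key", "dim", "daily_yield_kg", "breeding_status"]]

    rows = chosen.merge(
        day_info,
        left_on=["lactation_key", "as_of_dim"],
        right_on=["lactation_key", "dim"],
        how="left",
    )
    rows = rows[rows["breeding_status"] == "Open"]
    rows = rows.merge(targets, on="lactation_key", how="inner")
    rows = rows.merge(
        lactations[
            [
                "lactation_key",
                "herd_id",
                "parity_group",
                "age_days",
                "calving_season",
                "end_year",
            ]
        ],
        on="lactation_key",
        how="left",
    )
    rows["age_months"] = (rows["age_days"] / DAYS_PER_MONTH).round(1)
    rows["prev_year"] = rows["end_year"] - 1
    rows = rows.merge(
        hlcc,
        left_on=["herd_id", "prev_year", "parity_group"],
        right_on=["herd_id", "year", "parity_group"],
        how="left",
    ).merge(
        hm305,
        left_on=["herd_id", "prev_year"],
        right_on=["herd_id", "year"],
        how="left",
        suffixes=("", "_m305"),
    )
    herd_cols = [
        "herd_magnitude",
        "herd_time_to_peak",
        "herd_offset",
        "herd_decay",
        "herd_m305",
    ]
    rows = rows.dropna(subset=herd_cols)

    out = pd.DataFrame(
        {
            "moment": moment,
            "lactation_key": rows["lactation_key"],
            "dim_used": rows["as_of_dim"].astype(int),
            "magnitude": rows["magnitude"],
            "time_to_peak": rows["ramp"],
            "offset": rows["offset"],
            "decay": rows["decay"],
            "daily_yield_kg": rows["daily_yield_kg"],
            "age_months": rows["age_months"],
            "calving_season": rows["calving_season"],
            "parity_group": rows["parity_group"],
            "herd_magnitude": rows["herd_magnitude"],
            "herd_time_to_peak": rows["herd_time_to_peak"],
            "herd_offset": rows["herd_offset"],
            "herd_decay": rows["herd_decay"],
            "herd_m305": rows["herd_m305"],
            "decay_305": rows["decay_305"],
            "m305_target": rows["m305_target"],
        }
    )
    out["schema_version"] = SCHEMA_VERSION
    return out.reset_index(drop=True)
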
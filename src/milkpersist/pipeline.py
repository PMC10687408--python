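"""End-to-end pipeline: visits -> daily yields -> fitted curves -> edited
cohort -> insemination datasets -> evaluated prediction models.

At cohort scale the pipeline estimates curves only at the DIMs the analysis
consumes: every daily record inside an insemination window (fallback bound
to moment) and the DIM 304/305 target records.  This is the as-of-day
estimate the incremental procedure would produce at those days — the fit at
a DIM uses exactly the records up to and including it — computed without
fitting the hundreds of intermediate days the downstream analysis never
reads.  :func:`milkpersist.fitting.incremental_fit_series` provides the
full per-record series for single lactations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as ch
from . import fitting as ft
from .daily_yield import daily_table
from .prediction import EvaluationReport, ModelSpec, evaluate_model, split_train_test

__all__ = ["PipelineResult", "required_fit_dims", "fit_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_MOMENTS = (50, 75, 100, 125)
TARGET_DIMS = (304, 305)


@dataclass
class PipelineResult:
    daily: pd.DataFrame
    lactations: pd.DataFrame
    fits: pd.DataFrame
    exclusion_logs: dict[str, pd.DataFrame]
    hlcc: pd.DataFrame
    hm305: pd.DataFrame
    datasets: dict[int, pd.DataFrame]
    reports: dict[tuple[int, str], EvaluationReport] = field(default_factory=dict)


def required_fit_dims(dims: np.ndarray, moments=DEFAULT_MOMENTS) -> list[int]:
    """The as-of DIMs one lactation needs fitted.

    All record DIMs inside each moment's [fallback bound, moment] window
    (the dataset builder may fall back to any of them after the editing
    cascade) plus the 304/305 target records where present.
    """
    dims = np.asarray(dims)
    wanted: set[int] = set()
    for m in moments:
        lo = ch.FALLBACK_BOUNDS[m]
        wanted.update(int(d) for d in dims[(dims >= lo) & (dims <= m)])
    wanted.update(int(d) for d in dims[np.isin(dims, TARGET_DIMS)])
    return sorted(wanted)


def fit_cohort(
    daily: pd.DataFrame,
    lactations: pd.DataFrame,
    moments=DEFAULT_MOMENTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit curves for every lactation at its required as-of DIMs."""
    groups = lactations.set_index("lactation_key")["parity_group"]
    all_fits: list[ft.FittedCurve] = []
    for key, grp in daily.groupby("lactation_key", sort=False):
        pg = groups.get(key)
        if pg not in ("primiparous", "multiparous"):
            continue
        at_dims = required_fit_dims(grp["dim"].to_numpy(), moments)
        if not at_dims:
            continue
        prior = ft.default_prior(pg)
        all_fits.extend(ft.fit_at_dims(grp, at_dims, prior, lactation_key=key, seed=seed))
    return ft.fits_to_frame(all_fits)


def run_pipeline(
    visits: pd.DataFrame,
    cows: pd.DataFrame,
    moments=DEFAULT_MOMENTS,
    targets=("decay_305", "m305_target"),
    train_fraction: float = 0.8,
    cv_folds: int | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a visit-level dataset.

    Returns every intermediate table, the exclusion logs of the editing
    cascade, and an :class:`EvaluationReport` per (moment, target).
    """
    lact_all = ch.build_lactation_table(
        cows, _daily_for_lengths(visits, cows)
    )
    lact, lact_log = ch.lactation_level_filters(lact_all)
    logger.info("lactation filters: %d -> %d", len(lact_all), len(lact))

    kept_visits = visits[visits["lactation_key"].isin(lact["lactation_key"])]
    daily = daily_table(kept_visits, lact)
    daily = ch.assign_breeding_status(daily, lact)

    fits = fit_cohort(daily, lact, moments=moments, seed=seed)
    fits = fits[fits["converged"]]
    fits, fit_log = ch.post_fit_filters(fits, lact)

    final = ch.final_curve_table(fits, lact)
    hlcc, hm305 = ch.herd_year_aggregate(final)

    datasets: dict[int, pd.DataFrame] = {}
    reports: dict[tuple[int, str], EvaluationReport] = {}
    for m in moments:
        ds = ch.build_insemination_dataset(m, fits, daily, lact, hlcc, hm305)
        datasets[m] = ds
        if len(ds) < 30:
            logger.warning("moment %d: only %d rows; skipping model fit", m, len(ds))
            continue
        train, test = split_train_test(ds, fraction=train_fraction, seed=seed)
        for target in targets:
            spec = ModelSpec(target=target, moment=m)
            report, _ = evaluate_model(
                train, test, spec, cv_folds=cv_folds, seed=seed
            )
            reports[(m, target)] = report

    return PipelineResult(
        daily=daily,
        lactations=lact,
        fits=fits,
        exclusion_logs={"lactation": lact_log, "post_fit": fit_log},
        hlcc=hlcc,
        hm305=hm305,
        datasets=datasets,
        reports=reports,
    )


def _daily_for_lengths(visits: pd.DataFrame, cows: pd.DataFrame) -> pd.DataFrame:
    """Cheap per-lactation last-DIM table (lengths only, no 24-h yields)."""
    v = visits.drop(columns=["calving_date"], errors="ignore").merge(
        cows[["lactation_key", "calving_date"]], on="lactation_key", how="left"
    )
    dim = (v["visit_datetime"].dt.normalize() - v["calving_date"]).dt.days
    return pd.DataFrame({"lactation_key": v["lactation_key"], "dim": dim})
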
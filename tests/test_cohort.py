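"""Editing cascade, breeding status, herd-year aggregation and dataset
construction on constructed toy tables with known answers."""

import numpy as np
import pandas as pd
import pytest

from milkpersist.cohort import (
    assign_breeding_status,
    build_insemination_dataset,
    calving_season,
    herd_year_aggregate,
    lactation_level_filters,
    post_fit_filters,
)


def make_lactations(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "lactation_key": [f"c{i}" for i in range(n)],
            "herd_id": "H1",
            "parity": rng.integers(1, 4, size=n).astype(float),
            "parity_group": "multiparous",
            "age_days": rng.integers(700, 3000, size=n).astype(float),
            "lactation_length": rng.integers(280, 420, size=n).astype(float),
            "calving_date": pd.Timestamp("2021-01-10"),
            "next_calving_date": pd.NaT,
            "calving_season": "Winter",
            "end_year": 2021,
        }
    )


class TestSeasons:
    @pytest.mark.parametrize(
        "month,season",
        [(3, "Spring"), (5, "Spring"), (6, "Summer"), (8, "Summer"),
         (9, "Autumn"), (11, "Autumn"), (12, "Winter"), (1, "Winter"), (2, "Winter")],
    )
    def test_month_mapping(self, month, season):
        assert calving_season(month) == season


class TestLactationFilters:
    def test_missing_parity_counted(self):
        lact = make_lactations(100)
        lact.loc[lact.index[3], "parity"] = np.nan
        kept, log = lactation_level_filters(lact)
        assert log.loc[log["step"] == "missing_parity", "n_excluded"].iloc[0] == 1
        assert "c3" not in set(kept["lactation_key"])

    def test_uniform_ages_match_brute_force_percentile_filter(self):
        lact = make_lactations(100)
        lact["parity"] = 2.0
        lact["age_days"] = np.arange(1.0, 101.0)
        kept, log = lactation_level_filters(lact)
        # brute-force oracle on the same quantile definition
        q1, q99 = np.quantile(lact["age_days"], [0.01, 0.99])
        expect = ((lact["age_days"] < q1) | (lact["age_days"] > q99)).sum()
        step = log.loc[log["step"] == "extreme_age_within_parity"].iloc[0]
        assert step["n_excluded"] == expect == 2
        assert not kept["age_days"].isin([1.0, 100.0]).any()

    def test_identical_ages_drop_nothing(self):
        lact = make_lactations(50)
        lact["age_days"] = 900.0
        _, log = lactation_level_filters(lact)
        assert log.loc[log["step"] == "extreme_age_within_parity", "n_excluded"].iloc[0] == 0

    def test_empty_input_gives_zeroed_log(self):
        kept, log = lactation_level_filters(make_lactations(0))
        assert len(kept) == 0
        assert (log["n_excluded"] == 0).all()

    def test_log_counts_sum_to_dropped_rows(self):
        lact = make_lactations(200, seed=3)
        lact.loc[lact.index[:4], "parity"] = np.nan
        kept, log = lactation_level_filters(lact)
        assert log["n_excluded"].sum() == len(lact) - len(kept)


def make_fits(lact, seed=0, dims=(50, 75, 100, 125, 304, 305)):
    rng = np.random.default_rng(seed)
    rows = []
    for key in lact["lactation_key"]:
        for dim in dims:
            rows.append(
                (
                    key,
                    dim,
                    rng.normal(45, 6),
                    rng.normal(24, 3),
                    -0.5,
                    rng.normal(1.9e-3, 0.8e-3),
                    rng.gamma(4.0, 0.4),
                    dim,
                    True,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lactation_key", "as_of_dim", "magnitude", "ramp", "offset",
            "decay", "fit_rmse", "n_points", "converged",
        ],
    )


class TestPostFitFilters:
    def test_short_lactation_dropped_first(self):
        lact = make_lactations(20)
        lact["lactation_length"] = 340.0
        lact.loc[lact.index[0], "lactation_length"] = 200.0
        fits = make_fits(lact)
        kept, log = post_fit_filters(fits, lact)
        assert "c0" not in set(kept["lactation_key"])
        assert log.iloc[0]["step"] == "lactation_ends_before_305"
        assert log.iloc[0]["n_excluded"] == 6  # all 6 fitted rows of c0

    def test_injected_negative_decay_dropped(self):
        lact = make_lactations(20)
        lact["lactation_length"] = 340.0
        fits = make_fits(lact)
        fits.loc[fits.index[7], "decay"] = -1e-4
        kept, log = post_fit_filters(fits, lact)
        assert (kept["decay"] >= 0).all()
        assert log.loc[log["step"] == "negative_decay", "n_excluded"].iloc[0] >= 1

    def test_surviving_counts_match_brute_force_reapplication(self):
        lact = make_lactations(120, seed=5)
        lact["lactation_length"] = np.where(
            np.arange(len(lact)) % 10 == 0, 250.0, 350.0
        )
        fits = make_fits(lact, seed=5)
        # inject contamination
        fits.loc[fits.index[::37], "decay"] = -2e-4
        fits.loc[fits.index[::41], "fit_rmse"] = 30.0

        kept, log = post_fit_filters(fits, lact)

        # independent brute-force reapplication of the stated thresholds
        df = fits.merge(lact[["lactation_key", "lactation_length"]], on="lactation_key")
        df = df[df["lactation_length"] >= 305]
        df = df[df["decay"] >= 0]
        df = df[~(df["fit_rmse"] > np.quantile(df["fit_rmse"], 0.95))]
        ok = np.ones(len(df), dtype=bool)
        for col in ("magnitude", "ramp", "decay"):
            q1, q99 = np.quantile(df[col], [0.01, 0.99])
            ok &= ~((df[col] < q1) | (df[col] > q99)).to_numpy()
        df = df[ok]
        has_target = df[df["as_of_dim"].isin([304, 305])]["lactation_key"].unique()
        df = df[df["lactation_key"].isin(has_target)]

        assert len(kept) == len(df)
        assert set(kept["lactation_key"]) == set(df["lactation_key"])
        assert log["n_excluded"].sum() == len(fits) - len(kept)


class TestBreedingStatus:
    def daily(self, dims):
        return pd.DataFrame(
            {"lactation_key": "c0", "dim": dims, "daily_yield_kg": 30.0}
        )

    def lact(self, next_calving):
        return pd.DataFrame(
            {
                "lactation_key": ["c0"],
                "calving_date": [pd.Timestamp("2021-01-01")],
                "next_calving_date": [next_calving],
            }
        )

    def test_no_next_calving_is_never(self):
        out = assign_breeding_status(self.daily([10, 100, 200]), self.lact(pd.NaT))
        assert (out["breeding_status"] == "Never").all()

    def test_conception_at_dim_100_splits_open_and_bred(self):
        # next calving 382 days after calving -> conception at DIM 100
        next_cal = pd.Timestamp("2021-01-01") + pd.Timedelta(days=382)
        out = assign_breeding_status(
            self.daily(np.arange(90, 111)), self.lact(next_cal)
        )
        by_dim = out.set_index("dim")["breeding_status"]
        assert (by_dim.loc[:100] == "Open").all()  # record on the date is Open
        assert (by_dim.loc[101:] == "Bred").all()


class TestHerdYearAggregate:
    def final(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "lactation_key", "herd_id", "parity_group", "end_year",
                "magnitude", "ramp", "offset", "decay", "m305",
            ],
        )

    def test_single_lactation_summary_is_itself(self):
        final = self.final([("c0", "H1", "primiparous", 2021, 40.0, 25.0, -0.5, 1.5e-3, 9000.0)])
        hlcc, hm305 = herd_year_aggregate(final)
        assert hlcc.iloc[0]["herd_decay"] == 1.5e-3
        assert hm305.iloc[0]["herd_m305"] == 9000.0

    def test_mean_of_two_decays(self):
        final = self.final(
            [
                ("c0", "H1", "primiparous", 2021, 40, 25, -0.5, 1e-3, 9000.0),
                ("c1", "H1", "primiparous", 2021, 40, 25, -0.5, 3e-3, 11000.0),
            ]
        )
        hlcc, hm305 = herd_year_aggregate(final)
        assert hlcc.iloc[0]["herd_decay"] == pytest.approx(2e-3)
        assert hm305.iloc[0]["herd_m305"] == pytest.approx(10000.0)

    def test_matches_brute_force_group_means(self, rng):
        rows = []
        for i in range(200):
            rows.append(
                (
                    f"c{i}",
                    f"H{rng.integers(1, 4)}",
                    str(rng.choice(["primiparous", "multiparous"])),
                    int(rng.choice([2020, 2021])),
                    rng.normal(45, 5),
                    rng.normal(24, 3),
                    rng.normal(-0.5, 0.1),
                    rng.normal(2e-3, 5e-4),
                    rng.normal(10000, 800),
                )
            )
        final = self.final(rows)
        hlcc, hm305 = herd_year_aggregate(final)
        # brute-force pass over the keys
        for _, row in hlcc.iterrows():
            sub = final[
                (final["herd_id"] == row["herd_id"])
                & (final["end_year"] == row["year"])
                & (final["parity_group"] == row["parity_group"])
            ]
            assert row["herd_magnitude"] == pytest.approx(sub["magnitude"].mean())
            assert row["herd_decay"] == pytest.approx(sub["decay"].mean())
        for _, row in hm305.iterrows():
            sub = final[
                (final["herd_id"] == row["herd_id"]) & (final["end_year"] == row["year"])
            ]
            assert row["herd_m305"] == pytest.approx(sub["m305"].mean())


class TestInseminationDataset:
    def setup_tables(self, fit_dims, daily_dims=None):
        lact = make_lactations(1)
        lact["lactation_length"] = 340.0
        lact["end_year"] = 2021
        # conception far in the future: Open throughout
        lact["next_calving_date"] = pd.Timestamp("2022-06-01")
        fits = make_fits(lact, dims=fit_dims)
        daily = pd.DataFrame(
            {
                "lactation_key": "c0",
                "dim": list(daily_dims or fit_dims),
                "daily_yield_kg": 32.0,
            }
        )
        hlcc = pd.DataFrame(
            {
                "herd_id": ["H1"], "year": [2020], "parity_group": ["multiparous"],
                "herd_magnitude": [48.0], "herd_time_to_peak": [23.0],
                "herd_offset": [-0.5], "herd_decay": [2e-3],
            }
        )
        hm305 = pd.DataFrame({"herd_id": ["H1"], "year": [2020], "herd_m305": [10000.0]})
        return fits, daily, lact, hlcc, hm305

    def test_exact_moment_used_when_available(self):
        tables = self.setup_tables((50, 75, 100, 125, 305))
        ds = build_insemination_dataset(75, *tables)
        assert len(ds) == 1
        assert ds.iloc[0]["dim_used"] == 75

    def test_fallback_to_closest_earlier_day(self):
        tables = self.setup_tables((50, 74, 100, 125, 305))
        ds = build_insemination_dataset(75, *tables)
        assert ds.iloc[0]["dim_used"] == 74

    def test_no_row_when_window_empty(self):
        tables = self.setup_tables((47, 75, 100, 125, 305))
        ds = build_insemination_dataset(50, *tables)
        assert len(ds) == 0

    def test_dim_304_substitutes_for_missing_305(self):
        tables = self.setup_tables((50, 75, 100, 125, 304))
        ds = build_insemination_dataset(50, *tables)
        fits = tables[0]
        target = fits.loc[fits["as_of_dim"] == 304, "decay"].iloc[0]
        assert ds.iloc[0]["decay_305"] == pytest.approx(target)

    def test_bred_rows_excluded(self):
        tables = self.setup_tables((50, 75, 100, 125, 305))
        lact = tables[2]
        # conception at DIM 60: Bred at DIM 75, Open at DIM 50
        lact["next_calving_date"] = lact["calving_date"] + pd.Timedelta(days=60 + 282)
        assert len(build_insemination_dataset(75, *tables)) == 0
        assert len(build_insemination_dataset(50, *tables)) == 1

    def test_missing_previous_year_summary_drops_row(self):
        tables = self.setup_tables((50, 75, 100, 125, 305))
        hlcc = tables[3]
        hlcc["year"] = 2021  # same year as the lactation end: must not be used
        ds = build_insemination_dataset(50, tables[0], tables[1], tables[2], hlcc, tables[4])
        assert len(ds) == 0

    def test_invalid_moment_rejected(self):
        tables = self.setup_tables((50, 305))
        with pytest.raises(ValueError, match="moment"):
            build_insemination_dataset(60, *tables)
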
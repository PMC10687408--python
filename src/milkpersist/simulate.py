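"""Synthetic multi-herd robot-milking cohorts with known ground truth.

No public robot-visit dataset exists at the scale this pipeline targets, so
the package ships a generator that emulates one: multiple herds over
several calendar years, parity-dependent lactation-curve parameter
distributions with herd-level random effects, 2–4 robot visits per day at
irregular intervals, visit yields equal to the integral of the true curve
over the inter-visit interval plus noise, calving dates spread over the
year, and conception dates (282-day gestation) that define breeding status
and lactation length.  Ground truth — the generating curve, the true
305-day decay, M305 and the conception day — is emitted in a separate
table that pipeline stages never read.

The central design device is ``signal_fraction`` (``f``): the fraction of
the variance of the pipeline's 305-day decay target that is explained by
what is measurable in early lactation.  The early-lactation decay ``d0``
follows the population distribution; mid-lactation the cow's decay drifts
linearly, across a window placed just after the last candidate
insemination moment, to a late value ``d0 + delta``.  The shift ``delta``
has a mean-reverting structure whose coefficients are chosen so that the
*estimated* decay at DIM 305 comes out distributed as

    d305_hat = mu305 + sigma305 * ( sqrt(f) * z0 + sqrt(1-f) * eps )

with ``z0`` the z-score of ``d0`` and ``eps`` independent N(0,1) noise:
its population variance explained by early-lactation information equals
``f`` exactly, and its mean and SD reproduce observed 305-day decay
statistics (1.55e-3 / 2.41e-3 per day for primiparous / multiparous
cows).  The conversion from the wanted target distribution to the true
late decay uses the per-group ``fit_absorption`` constant (see
:class:`ParityGroupLcc`).  With ``f = 1`` the late decay is an exact
affine function of the early one (fully predictable); with low ``f`` late
persistency is mostly driven by factors invisible at the insemination
moment — the regime in which persistency prediction is intrinsically
hard.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .milkbot import milkbot_curve

__all__ = [
    "ParityGroupLcc",
    "SimulationConfig",
    "FIXTURE_SCALES",
    "simulate_population",
    "make_fixture",
    "daily_records_from_curve",
    "true_yield",
]


@dataclass(frozen=True)
class ParityGroupLcc:
    """Population distribution of the four curve parameters for one group.

    ``decay305_mean`` / ``decay305_sd`` anchor the distribution of the
    *estimated* 305-day decay (the pipeline's target).  ``fit_absorption``
    is a generator design constant: the share of a late-lactation decay
    shift that a full-lactation single-decay fit absorbs into its decay
    estimate (the remainder is soaked up by the other parameters).  It
    depends only on the curve family, the drift window and the fitter, and
    converts the wanted target distribution into the required true
    late-decay distribution.
    """

    mean: tuple[float, float, float, float]
    sd: tuple[float, float, float, float]
    decay305_mean: float
    decay305_sd: float
    fit_absorption: float = 0.71


#: Population anchors: primiparous curves ramp slower, peak lower, decline
#: more slowly than multiparous ones; 305-day decay runs higher and tighter
#: than the early-lactation decay distribution.
PRIMIPAROUS_LCC = ParityGroupLcc(
    mean=(38.2, 28.2, -0.50, 1.4e-3),
    sd=(6.0, 2.4, 2.5e-5, 0.9e-3),
    decay305_mean=1.55e-3,
    decay305_sd=0.7e-3,
    fit_absorption=0.70,
)
MULTIPAROUS_LCC = ParityGroupLcc(
    mean=(51.2, 21.0, -0.53, 1.9e-3),
    sd=(7.5, 3.8, 0.36, 1.0e-3),
    decay305_mean=2.41e-3,
    decay305_sd=0.8e-3,
    fit_absorption=0.72,
)

_PARAM_LO = np.array([5.0, 1.0, -20.0, -0.005])
_PARAM_HI = np.array([120.0, 80.0, 20.0, 0.02])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference study cohort: 10 herds x 150 cows per
    calendar year over 3 years, Holstein-scale curve parameters, 2-4 robot
    visits per day, and a conception process (herd voluntary waiting
    period + 21-day cycles) that leaves a realistic mix of Open / Bred /
    Never records at every insemination moment.
    """

    n_herds: int = 10
    cows_per_herd: int = 150
    years: int = 3
    start_year: int = 2019
    parity_probs: tuple[float, ...] = (0.31, 0.26, 0.19, 0.14, 0.10)
    primiparous: ParityGroupLcc = field(default_factory=lambda: PRIMIPAROUS_LCC)
    multiparous: ParityGroupLcc = field(default_factory=lambda: MULTIPAROUS_LCC)
    # herd-level random-effect SDs for (magnitude, ramp, offset, decay)
    herd_sd: tuple[float, float, float, float] = (3.0, 1.0, 0.0, 0.3e-3)
    visits_per_day_range: tuple[float, float] = (2.0, 4.0)
    gap_shape: float = 4.0  # Gamma shape of inter-visit gaps (CV = 1/2)
    visit_noise_sd: float = 0.7  # additive kg per visit
    day_cv: float = 0.06  # multiplicative day-to-day yield variation (population mean)
    day_cv_dispersion: float = 0.5  # between-cow CV of the day-to-day noise level
    vwp_range: tuple[float, float] = (50.0, 80.0)  # herd voluntary waiting period
    cycle_days: float = 21.0
    p_conception: float = 0.35  # per 21-day cycle
    max_cycles: int = 8
    p_never_bred: float = 0.06
    dry_period_days: float = 60.0
    never_end_range: tuple[float, float] = (330.0, 430.0)
    gestation_days: float = 282.0
    signal_fraction: float = 0.35
    drift_window: tuple[float, float] = (126.0, 170.0)
    post_conception_decay_shift: float = 0.0  # speculative; off by default
    missing_parity_frac: float = 0.004
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_herds < 1:
            problems.append("n_herds must be >= 1")
        if self.cows_per_herd < 1:
            problems.append("cows_per_herd must be >= 1")
        if self.years < 1:
            problems.append("years must be >= 1")
        if not np.isclose(sum(self.parity_probs), 1.0):
            problems.append("parity_probs must sum to 1")
        if self.visits_per_day_range[0] <= 0:
            problems.append("visits_per_day_range must be positive")
        if not (0.0 <= self.signal_fraction <= 1.0):
            problems.append("signal_fraction must be in [0, 1]")
        if self.visit_noise_sd < 0 or self.day_cv < 0:
            problems.append("noise parameters must be >= 0")
        if self.drift_window[1] <= self.drift_window[0]:
            problems.append("drift_window must be an increasing interval")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("primiparous", "multiparous"):
            grp = raw[key]
            raw[key] = ParityGroupLcc(
                mean=tuple(grp["mean"]),
                sd=tuple(grp["sd"]),
                decay305_mean=grp["decay305_mean"],
                decay305_sd=grp["decay305_sd"],
                fit_absorption=grp["fit_absorption"],
            )
        for key, val in list(raw.items()):
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


def _within_group_signal_fraction(config: SimulationConfig) -> float:
    """Convert the pooled signal fraction into a within-parity-group one.

    ``signal_fraction`` is the proportion of pooled decay-305 target
    variance explained by all measured predictors.  Parity group is itself
    a predictor, and the between-group separation of the 305-day decay
    means is always fully explained by its dummy; only the within-group
    part is tunable.  With group shares p_g, target means mu_g and SDs
    s_g:

        V_b = sum p_g (mu_g - mu_bar)^2,   V_w = sum p_g s_g^2,
        f_within = (f (V_b + V_w) - V_b) / V_w

    A pooled fraction below V_b / (V_b + V_w) is unattainable (the parity
    means alone explain that much); f_within is then floored at 0.
    """
    p1 = config.parity_probs[0]
    groups = (config.primiparous, config.multiparous)
    shares = np.array([p1, 1.0 - p1])
    mus = np.array([g.decay305_mean for g in groups])
    sds = np.array([g.decay305_sd for g in groups])
    mu_bar = float(shares @ mus)
    v_b = float(shares @ (mus - mu_bar) ** 2)
    v_w = float(shares @ sds**2)
    f_within = (config.signal_fraction * (v_b + v_w) - v_b) / v_w
    return float(np.clip(f_within, 0.0, 1.0))


def _drift_integral(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Integral from 0 to t of the linear 0->1 drift ramp on [t0, t1]."""
    t = np.asarray(t, dtype=float)
    ramp = (t - t0) ** 2 / (2.0 * (t1 - t0))
    out = np.where(t <= t0, 0.0, np.where(t <= t1, ramp, (t1 - t0) / 2.0 + (t - t1)))
    return out


def true_yield(
    t,
    lcc: np.ndarray,
    delta: float = 0.0,
    drift_window: tuple[float, float] = (130.0, 200.0),
):
    """True (noise-free) daily yield of a drifting-decay MilkBot curve."""
    a, b, c, d0 = lcc
    t = np.asarray(t, dtype=float)
    cum_decay = d0 * t + delta * _drift_integral(t, *drift_window)
    y = a * (1.0 - np.exp((c - t) / b) / 2.0) * np.exp(-cum_decay)
    return np.maximum(y, 0.0)


def _simpson_interval_yield(t_edges: np.ndarray, yield_fn) -> np.ndarray:
    """Integral of the yield curve over each [t_i, t_{i+1}] (Simpson's rule)."""
    t0, t1 = t_edges[:-1], t_edges[1:]
    mid = 0.5 * (t0 + t1)
    h = t1 - t0
    return h / 6.0 * (yield_fn(t0) + 4.0 * yield_fn(mid) + yield_fn(t1))


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: ``(visits, cows, ground_truth)``.

    ``visits`` is the robot-visit table consumed by the pipeline; ``cows``
    has one row per lactation (identity, parity, dates); ``ground_truth``
    holds the generating parameters and is for evaluation only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    f_within = _within_group_signal_fraction(config)

    herd_effects = {
        h: rng.normal(0.0, config.herd_sd) for h in range(config.n_herds)
    }
    herd_vwp = {
        h: rng.uniform(*config.vwp_range) for h in range(config.n_herds)
    }

    parities = np.arange(1, len(config.parity_probs) + 1)
    year0 = config.start_year

    visit_time, visit_yield, visit_counts = [], [], []
    cow_rows, truth_rows = [], []

    counter = 0
    for h in range(config.n_herds):
        herd_id = f"H{h + 1:02d}"
        eff = herd_effects[h]
        vwp = herd_vwp[h]
        for year in range(config.years):
            for _ in range(config.cows_per_herd):
                counter += 1
                parity = int(rng.choice(parities, p=np.asarray(config.parity_probs)))
                group = config.primiparous if parity == 1 else config.multiparous
                key = f"{herd_id}C{counter:05d}_L{parity}"
                cow_id = f"{herd_id}C{counter:05d}"

                mean = np.asarray(group.mean)
                sd = np.asarray(group.sd)
                herd_sd = np.asarray(config.herd_sd)
                resid_sd = np.sqrt(np.maximum(sd**2 - herd_sd**2, 0.0))
                lcc = np.clip(
                    mean + eff + rng.normal(0.0, resid_sd), _PARAM_LO, _PARAM_HI
                )
                d0 = lcc[3]
                z0 = (d0 - mean[3]) / sd[3]
                eps = rng.standard_normal()
                # Late-decay shift with mean reversion, scaled so the
                # *estimated* 305-day decay comes out as
                #   decay305_mean + decay305_sd (sqrt(f) z0 + sqrt(1-f) eps),
                # i.e. its variance explained by early-lactation information
                # equals the signal fraction f exactly.
                lam = group.fit_absorption
                delta = (
                    (group.decay305_mean - mean[3])
                    + (np.sqrt(f_within) * group.decay305_sd - sd[3]) * z0
                    + np.sqrt(1.0 - f_within) * group.decay305_sd * eps
                ) / lam
                d305 = float(np.clip(d0 + delta, 1e-4, _PARAM_HI[3]))
                delta = d305 - d0

                # conception process
                conception_dim = np.nan
                if rng.random() >= config.p_never_bred:
                    for cyc in range(config.max_cycles):
                        if rng.random() < config.p_conception:
                            conception_dim = (
                                vwp
                                + cyc * config.cycle_days
                                + rng.uniform(0.0, config.cycle_days)
                            )
                            break
                if np.isfinite(conception_dim):
                    if config.post_conception_decay_shift:
                        delta += config.post_conception_decay_shift
                    end_dim = conception_dim + config.gestation_days - config.dry_period_days
                else:
                    end_dim = rng.uniform(*config.never_end_range)
                end_dim = float(end_dim)

                # calendar placement and cow age
                calving = pd.Timestamp(year0 + year, 1, 1) + pd.Timedelta(
                    days=int(rng.integers(0, 365))
                )
                age_days = 730.0 + (parity - 1) * 405.0 + rng.normal(0.0, 40.0)
                birth = calving - pd.Timedelta(days=round(age_days))
                next_calving = (
                    calving + pd.Timedelta(days=round(conception_dim + config.gestation_days))
                    if np.isfinite(conception_dim)
                    else pd.NaT
                )

                # robot visits: Gamma-distributed gaps around 24/visits_per_day h
                v_rate = rng.uniform(*config.visits_per_day_range)
                mean_gap_h = 24.0 / v_rate
                n_gaps = int(end_dim * 24.0 / mean_gap_h * 1.4) + 20
                gaps = rng.gamma(
                    config.gap_shape, mean_gap_h / config.gap_shape, size=n_gaps
                )
                times_h = np.cumsum(gaps)
                times_h = times_h[times_h <= end_dim * 24.0]
                if times_h.size < 2:
                    continue
                t_days = times_h / 24.0
                edges = np.concatenate([[0.0], t_days])
                milk = _simpson_interval_yield(
                    edges,
                    lambda tt: true_yield(tt, lcc, delta, config.drift_window),
                )
                day_idx = np.floor(t_days).astype(int)
                # cows differ in how erratic their day-to-day yields are
                # (health events, oestrus, robot behaviour)
                if config.day_cv_dispersion > 0:
                    shape = 1.0 / config.day_cv_dispersion**2
                    cow_cv = config.day_cv * rng.gamma(shape, 1.0 / shape)
                else:
                    cow_cv = config.day_cv
                day_mult = 1.0 + rng.normal(
                    0.0, cow_cv, size=int(day_idx.max()) + 1
                )
                noisy = milk * day_mult[day_idx] + rng.normal(
                    0.0, config.visit_noise_sd, size=milk.size
                )
                noisy = np.maximum(noisy, 0.0)

                visit_time.append(
                    calving.to_datetime64()
                    + (times_h * 3.6e12).astype("timedelta64[ns]")
                )
                visit_yield.append(noisy)
                visit_counts.append(times_h.size)

                cow_rows.append(
                    (key, cow_id, herd_id, float(parity), birth, calving, next_calving)
                )
                truth_rows.append(
                    (
                        key,
                        lcc[0],
                        lcc[1],
                        lcc[2],
                        d0,
                        delta,
                        d305,
                        conception_dim,
                        end_dim,
                    )
                )

    counts = np.asarray(visit_counts, dtype=int)
    lact_meta = list(zip(*cow_rows))  # columns of the per-lactation table
    visits = pd.DataFrame(
        {
            "herd_id": np.repeat(np.array(lact_meta[2], dtype=object), counts),
            "cow_id": np.repeat(np.array(lact_meta[1], dtype=object), counts),
            "parity": np.repeat(np.array(lact_meta[3], dtype=float), counts),
            "birth_date": np.repeat(
                np.array(lact_meta[4], dtype="datetime64[ns]"), counts
            ),
            "calving_date": np.repeat(
                np.array(lact_meta[5], dtype="datetime64[ns]"), counts
            ),
            "visit_datetime": np.concatenate(visit_time),
            "yield_kg": np.concatenate(visit_yield),
            "lactation_key": np.repeat(np.array(lact_meta[0], dtype=object), counts),
        }
    )
    visits["birth_date"] = pd.to_datetime(visits["birth_date"])
    visits["calving_date"] = pd.to_datetime(visits["calving_date"])
    visits["visit_datetime"] = pd.to_datetime(visits["visit_datetime"])

    cows = pd.DataFrame(
        cow_rows,
        columns=[
            "lactation_key",
            "cow_id",
            "herd_id",
            "parity",
            "birth_date",
            "calving_date",
            "next_calving_date",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "lactation_key",
            "magnitude",
            "ramp",
            "offset",
            "decay_early",
            "decay_delta",
            "decay305_true",
            "conception_dim",
            "end_dim",
        ],
    )
    # true M305: numeric integral of the drifting-decay curve over [0, 305]
    grid = np.linspace(0.0, 305.0, 1221)
    m305_true = np.empty(len(truth))
    for i, row in enumerate(truth.itertuples(index=False)):
        y = true_yield(
            grid,
            np.array([row.magnitude, row.ramp, row.offset, row.decay_early]),
            row.decay_delta,
            config.drift_window,
        )
        m305_true[i] = np.trapezoid(y, grid)
    truth["m305_true"] = m305_true

    # a small fraction of lactations lose their parity record
    if config.missing_parity_frac > 0 and len(cows):
        n_miss = int(round(config.missing_parity_frac * len(cows)))
        if n_miss:
            miss_idx = rng.choice(len(cows), size=n_miss, replace=False)
            cows.loc[cows.index[miss_idx], "parity"] = np.nan
            missing_keys = cows.iloc[miss_idx]["lactation_key"]
            visits.loc[visits["lactation_key"].isin(missing_keys), "parity"] = np.nan

    return visits, cows, truth


#: Named fixture scales: (n_herds, cows_per_herd, years).
FIXTURE_SCALES = {
    "tiny": (2, 20, 1),
    "small": (5, 100, 2),
    "paper_like": (10, 150, 3),
}


def make_fixture(scale: str, seed: int, outdir) -> dict[str, Path]:
    """Write a visit CSV + ground-truth CSV + config JSON bundle.

    ``tiny`` runs in seconds and exercises the plumbing; ``small`` is
    enough for end-to-end statistics; ``paper_like`` echoes the reference
    study's per-moment row counts at roughly 1/10 scale.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    n_herds, cows_per_herd, years = FIXTURE_SCALES[scale]
    config = SimulationConfig(
        n_herds=n_herds, cows_per_herd=cows_per_herd, years=years, seed=seed
    )
    visits, cows, truth = simulate_population(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": outdir / f"{scale}_visits.csv",
        "cows": outdir / f"{scale}_cows.csv",
        "truth": outdir / f"{scale}_truth.csv",
        "config": outdir / f"{scale}_config.json",
    }
    visits.to_csv(paths["visits"], index=False)
    cows.to_csv(paths["cows"], index=False)
    truth.to_csv(paths["truth"], index=False)
    paths["config"].write_text(config.to_json())
    return paths


def daily_records_from_curve(
    lcc,
    dims,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    lactation_key="sim",
) -> pd.DataFrame:
    """Direct daily records from a (non-drifting) MilkBot curve + noise.

    Convenience generator for fitting studies: daily yield at each DIM is
    the curve value plus independent N(0, noise_sd) noise.
    """
    lcc_arr = np.asarray(
        lcc if not hasattr(lcc, "as_array") else lcc.as_array(), dtype=float
    )
    dims = np.asarray(dims, dtype=float)
    y = milkbot_curve(dims, *lcc_arr)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, size=dims.size)
    return pd.DataFrame(
        {
            "lactation_key": lactation_key,
            "dim": dims.astype(int),
            "daily_yield_kg": y,
        }
    )
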
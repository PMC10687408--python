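# Methods

## The model

Daily milk yield over a lactation is described by the MilkBot curve

    Y(t) = a (1 − e^{(c−t)/b} / 2) e^{−d t},

t in days in milk (DIM).  The magnitude *a* (kg/day) scales the curve, the
ramp *b* (days) is the time constant of the early rise, the offset *c*
(days) shifts the ramp, and the decay *d* (1/day) is the exponential
decline rate of late lactation.  Yields are floored at 0 kg: the raw
expression is negative for t far below the offset, a region the fitter
never sees (daily records start at DIM 1).

Persistency is the half-life of production in the declining phase,
0.693/d days.  The constant is kept as the conventional printed 0.693
rather than ln 2, so that the standard worked examples reproduce exactly
(e.g. a 40-kg peak with persistency 300 halves to 20.003 kg after 300
days); the discrepancy with a true half-life is 0.02%.

The 305-day cumulative yield has the closed form

    M305 = a(1 − e^{−305 d})/d + a b e^{c/b} (−1 + e^{−305(1/b + d)}) / (2 + 2 b d),

identical to ∫₀³⁰⁵ Y dt; at d = 0 the first term takes its limit 305·a.
Correctness is referenced against adaptive quadrature of Y (relative
tolerance 1e-6 over the population 5%–95% parameter envelope).  Peak
location uses a dense 0.1-day grid on [0, 500] with bounded local
refinement — robust rather than fast, since no analytic peak is used
anywhere downstream.

## 24-h daily yields from robot visits

AMS cows milk 2–4 times/day at irregular intervals; a visit's weight is
the milk accumulated since the previous visit.  The 24-h yield at visit v
is a rate estimate: the total weight of up to 12 visits ending at v that
each have a recorded predecessor, divided by the time from the predecessor
of the window's first visit to v, scaled to 24 h.  This reproduces the
constant-rate limit exactly and is conserved under splitting or merging of
visits.  The published reference procedure for AMS 24-h yields is not
reproduced verbatim here (its per-interval weighting details are not in
the public domain); the rate definition is this package's documented
stand-in.  The last visit of each calendar day defines that day's daily
yield.  Calving day is DIM 0; daily records start at DIM 1; days without
visits are left missing, never imputed.

## Incremental prior-regularised fitting

Decision support needs the curve *as of* each day, so for a given day the
fit uses exactly the daily records up to and including it.  The estimate
minimises

    Σ_i (y_i − Y(t_i; θ))² + Σ_p ((θ_p − μ_p)/σ_p)²,

i.e. a MAP estimate under independent Gaussian priors with the noise
variance absorbed into the prior σ's.  The penalty is fixed while the data
term grows, so the prior dominates when records are few and washes out as
the lactation progresses.  Default priors are population values per parity
group (primiparous 38.2/28.2/−0.50/1.4e-3 with SDs 6.0/2.4/2.5e-5/0.9e-3;
multiparous 51.2/21.0/−0.53/1.9e-3 with SDs 7.5/3.8/0.36/1.0e-3).  The
primiparous offset SD is so small that the offset is effectively frozen at
−0.50 d, mirroring how these populations are conventionally parameterised;
`freeze_offset` makes the same behaviour explicit.  Because the ramp prior
stays mildly informative even against a full noise-free lactation, the two
parity priors leave a ~1% residual imprint on the day-305 decay; the
prior-washout property is therefore stated (and tested) for priors the
data can dominate.

Optimisation: trust-region reflective least squares with an analytic
Jacobian, bounds a ∈ (5, 120), b ∈ (1, 80), c ∈ (−20, 20),
d ∈ (−0.005, 0.02) (negative decay is allowed in fitting and removed later
by the editing cascade, as rising "curves" do occur with few records), and
parameter scaling (10, 10, 1, 1e-3).  On failure up to 3 seeded random
restarts inside the bounds are tried; if all fail the prior means are
returned flagged non-converged and excluded downstream.  Incremental
series warm-start each day from the previous day's solution.

At cohort scale the pipeline fits only the as-of DIMs the analysis reads:
daily records inside each insemination window (fallback bound…moment) plus
the DIM 304/305 target records — identical estimates to the full
per-record series at those days, at ~2% of the cost.  The full series
remains available (`incremental_fit_series`) and is exercised on single
lactations in the tests.

## Editing cascade

Filters run in a fixed order with per-step exclusion logging.
Lactation-level: (1) missing parity; (2) age at calving outside the
(1%, 99%) percentiles computed within parity; (3) lactation length above
the 99% percentile.  Post-fit, on the per-record curve table: (1)
lactations ending before DIM 305 (no target); (2) records with negative
decay; (3) fit RMSE above the 95% percentile; (4) magnitude, time to peak
or decay outside (1%, 99%); (5) lactations lacking both a DIM-305 and a
DIM-304 curve (304 is the only accepted substitute).  Percentiles are
linear-interpolation quantiles; thresholds are strict exceedances, so
degenerate distributions drop nothing.  Percentile thresholds are computed
over the fitted rows present in the run.

Breeding status: conception = next calving − 282 d (fixed gestation; breed
differences not modelled).  A record dated exactly on the conception date
counts as Open (Bred requires conception strictly earlier).  Cows with no
subsequent calving are Never and excluded from the model datasets — the
target population is cows whose insemination decision is still open.

Herd covariates: lactations aggregate to the calendar year of their last
daily record; HLCC means per herd×year×parity group, HM305 per herd×year
(not per parity group).  Model rows join summaries from their end-year − 1
only — the herd information actually available at decision time — and rows
without previous-year summaries are dropped.

Dataset construction per moment m ∈ {50, 75, 100, 125}: the curve at
exactly DIM m, else the closest earlier fitted day no earlier than the
fallback bound (48, 74, 98, 122); daily yield at that day; age in months =
age_days / 30.4375 rounded to 1 decimal; calving season by calving month
(3–5 Spring, 6–8 Summer, 9–11 Autumn, 12–2 Winter); parity group; HLCC and
HM305.  Target: decay of the day-305 (or 304) curve.

## Prediction models

Per moment, rows split 80/20 at the cow-parity-record level (simple random
split, seeded).  Continuous predictors are z-scored with training
mean/SD — exactly-constant columns are dropped with a warning — and season
/ parity group are dummy-coded against Winter / primiparous.  Plain OLS
(statsmodels) supplies coefficients and conventional SEs; herd enters
through HLCC/HM305 as fixed covariates rather than a random effect, so the
model transfers to unseen herds.  10-fold cross-validation on the training
set is reporting-only: OLS has no hyperparameters.  Evaluation on the
held-out rows: R² = 1 − SSres/SStot, RMSE, MAE, and MAPE over rows with
non-zero observations (decay targets are strictly positive after
filtering; excluded rows are counted).  Standardised coefficients are
ranked by |estimate| with alphabetical tie-breaks; a funnel plot is
available.

## Synthetic cohort generator

The generator emulates what the pipeline needs from real AMS data: herds
with random curve-parameter effects (SDs 3.0/1.0/0/0.3e-3), cow curves per
parity group at the population values above (truncated to the fitting
bounds, so a few truly negative early decays occur and exercise the
cascade), 2–4 visits/day with Gamma-distributed gaps (CV ½), visit weights
equal to the integral of the true curve over the inter-visit interval
(Simpson) plus 0.7 kg additive noise and a multiplicative day effect
(mean CV 6%, itself varying between cows with dispersion 0.5 — cows differ
in how erratic they are, which is what the RMSE edit should be ranking),
calving dates uniform over the year, a conception process (herd voluntary
waiting period 50–80 d, 21-day cycles, 35% risk/cycle, 8 cycles, 6% never
bred) that yields realistic Open/Bred/Never mixes and ties lactation
length to conception (dry-off 60 d before the next calving; never-bred
cows end at 330–430 d), and a small fraction (0.4%) of missing parities.

The central device is `signal_fraction` f: the proportion of the variance
of the *estimated* day-305 decay that is explained by the measured
predictors.  Parity group is a predictor, so the between-group separation
of the day-305 decay means (anchored at 1.55e-3 vs 2.41e-3/day, SDs
0.7e-3/0.8e-3) is always explained; f is converted internally to a
within-group fraction (pooled fractions below the between-group share,
about 0.21 at the default parity mix, floor at zero within-group signal).
Mechanically, each cow's decay drifts linearly from its early value d0
across DIM 126–170 (just after the last insemination moment) to a late
value d0 + δ, with δ mean-reverting: its coefficients are chosen so the
*fitted* day-305 decay is distributed μ + σ(√f·z0 + √(1−f)·ε) with z0 the
z-score of d0.  The conversion uses the per-group `fit_absorption`
constant (0.70/0.72) — the share of a late decay shift that a
full-lactation single-decay fit absorbs into its decay estimate, a
property of the curve family, drift window and fitter that was measured
once by simulation and is fixed as part of the generator design.  With
f = 1 the late decay is an exact affine function of the early one; the
default f = 0.35 puts the pipeline's held-out decay-305 R² in the
0.27–0.41 range at study scale while the M305 control models sit at
0.89–0.97 — the qualitative regime of interest: cumulative yield
predictable, late slope not.  A `post_conception_decay_shift` knob exists
for a pregnancy effect on persistency but defaults to 0: no quantitative
estimate of that effect is established, so it is documented as
speculative.

What the generator does *not* emulate: disease/culling dynamics beyond the
simple end-of-lactation rules, milk composition, genetics/pedigree,
seasonal feed effects on the curve shape, robot-specific log artefacts,
and timezone/clock irregularities.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and that its conclusions follow
from the stated information structure — not that real herds have
signal_fraction 0.35.

## Problem sizes and numerics

The reference study cohort is 10 herds × 150 cows/year × 3 calendar years
(~4,500 lactations, ~4.5 M visits), the package's default; it runs the
full pipeline in a few minutes single-core and gives test sets of ~140–370
rows per moment.  Reported accuracy bands are means over the four moments
(single-moment test R² at this scale carries sampling noise of ±0.05).
Tests use smaller cohorts (3 × 40 × 3) for structural checks.  Quantile
definitions follow numpy's linear interpolation; the d = 0 branch of M305
avoids the 0/0 limit analytically; Simpson integration over inter-visit
gaps (≤ half a day) keeps conservation errors below 1e-5 relative.

## Known limitations

* The 24-h yield is a rate estimate, not the certified reference formula.
* The editing cascade's percentile thresholds depend on the set of fitted
  records present, as they do in any concrete run of the method.
* Fitted decay at early DIMs is strongly prior-shrunk; its sampling error
  is not propagated into the prediction models (the models see point
  estimates, as in the original analysis design).
* OLS standard errors ignore within-herd correlation by design (herd
  effects enter as covariates).
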
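# milkpersist

Can a dairy farmer, at the moment the insemination decision is made, know
how *persistent* the current lactation will turn out to be?  Persistency —
the half-life of daily milk production in the declining stage of lactation
— decides which cows are good candidates for an extended voluntary waiting
period: persistent cows keep producing and can safely be bred later.  The
catch is that persistency for day 305 of lactation has to be predicted from
what is measurable at days 50–125.

`milkpersist` implements that analysis end-to-end for robot-milking (AMS)
herd data, as a tested, reusable Python library:

* **MilkBot curve engine** — the four-parameter lactation curve

  ```
  Y(t) = a · (1 − e^((c−t)/b) / 2) · e^(−d·t)
  ```

  with magnitude *a* (kg/day), ramp *b* (days), offset *c* (days) and decay
  *d* (1/day); persistency = 0.693 / d (days); closed-form 305-day
  cumulative yield M305 = ∫₀³⁰⁵ Y(t) dt.
* **24-h daily yields** from robot-visit records (rate over a trailing
  window of up to 12 milkings, ICAR-style).
* **Prior-regularised incremental fitting** — for every day of lactation,
  the curve is re-estimated from the records up to that day by penalised
  least squares (MAP under Gaussian priors per parity group), so early
  estimates shrink toward population values and the prior washes out as
  records accumulate.
* **Editing cascade** — lactation-level filters (missing parity, extreme
  age within parity, extreme lactation length), post-fit filters (lactation
  shorter than 305 d, negative decay, RMSE above the 95% percentile,
  extreme curve parameters, missing day-305/304 curve), with a full
  exclusion log.
* **Breeding status** — conception back-calculated as next calving − 282 d;
  records are Open / Bred / Never, and only Open records enter the models.
* **Herd-year covariates** — herd×year×parity-group curve means (HLCC) and
  herd×year M305 means (HM305), joined from the *previous* calendar year.
* **Prediction models** — OLS on standardised predictors per insemination
  moment (DIM 50/75/100/125), target = decay at DIM 305 (with M305 as a
  methodological control), evaluated on a held-out 20% split with R², RMSE,
  MAE, MAPE and 10-fold cross-validation.
* **Synthetic cohort generator** — multi-herd robot-visit datasets with
  known ground truth, including a `signal_fraction` knob that sets how much
  of the day-305 decay is knowable in early lactation.

No public robot-visit dataset exists at this granularity, so the generator
is a first-class part of the package: every pipeline stage is validated by
parameter recovery against ground truth it has never seen.

## Worked example

```python
import numpy as np
from milkpersist import (
    LactationCurveCharacteristics, persistency_from_decay, m305,
    SimulationConfig, simulate_population, run_pipeline,
)

# curve mathematics on population-mean parameters
lcc = LactationCurveCharacteristics(magnitude=38.2, ramp=28.2,
                                    offset=-0.50, decay=1.4e-3)
print(round(persistency_from_decay(1.55e-3)))   # 447  (days; primiparous)
print(round(persistency_from_decay(2.41e-3)))   # 288  (days; multiparous)
print(round(m305(lcc)))                          # 8974 (kg in 305 days)

# a small synthetic study: 3 herds x 40 cows/year x 3 years
cfg = SimulationConfig(n_herds=3, cows_per_herd=40, years=3, seed=7)
visits, cows, truth = simulate_population(cfg)
result = run_pipeline(visits, cows, seed=7)
for m in (50, 75, 100, 125):
    r = result.reports[(m, "decay_305")]
    rm = result.reports[(m, "m305_target")]
    print(m, round(r.r2, 2), round(r.mape, 2), "| m305", round(rm.r2, 2))
# 50 0.05 0.24 | m305 0.84
# 75 0.52 0.28 | m305 0.94
# 100 0.32 0.22 | m305 0.94
# 125 0.5 0.14 | m305 0.93
```

Per moment this prints the held-out R² and MAPE of the decay-305 model and
the R² of the M305 control.  On a cohort this small the decay R² values
are noisy (test sets of ~20–40 rows); at study scale (the default
configuration, ~4,500 lactations) they tighten to ≈ 0.32–0.41 with a mean
of ≈ 0.35 under the default `signal_fraction=0.35`.  The M305 control
models on the same rows reach R² ≈ 0.9 — the cumulative yield is essentially set by
early-lactation information, but the *slope* of late lactation is not.
That asymmetry is the analysis' central finding, and the generator can
produce both regimes (`signal_fraction=1.0` makes late decay fully
knowable, and prediction accuracy then rises steadily with later
insemination moments).

A thin CLI mirrors the library: `milkpersist simulate`, `milkpersist run`,
`milkpersist predict` (see `--help`).

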
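"""Closed-form MilkBot lactation-curve mathematics.

The MilkBot model describes the daily milk yield of a dairy cow as

    Y(t) = a * (1 - exp((c - t)/b) / 2) * exp(-d * t)

where ``t`` is days in milk (DIM) and the four lactation-curve
characteristics (LCC) are

* ``a`` — magnitude (scale) of production, kg/day,
* ``b`` — ramp time-constant of the early-lactation rise, days (often
  reported in the field as "time to peak yield"),
* ``c`` — offset, a time shift of the ramp, days,
* ``d`` — decay, the exponential decline rate of the late lactation, 1/day.

The decay maps onto *persistency*, the half-life of milk production in the
declining stage of lactation: the number of days for daily yield to halve,
``0.693 / d``.  The 0.693 constant is kept literally (rather than ln 2) so
that the conventional printed examples reproduce exactly.

This module provides yield evaluation, the persistency/decay transforms,
the closed-form 305-day cumulative yield (M305) and peak localisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "HALF_LIFE_CONSTANT",
    "LactationCurveCharacteristics",
    "milkbot_curve",
    "milk_yield",
    "persistency_from_decay",
    "decay_from_persistency",
    "half_life_decline",
    "m305",
    "peak_summary",
]

#: Half-life constant of the persistency transform.  Kept as the printed
#: convention 0.693 rather than ln(2) = 0.693147... .
HALF_LIFE_CONSTANT = 0.693


@dataclass(frozen=True)
class LactationCurveCharacteristics:
    """The four MilkBot parameters plus the RMSE of the fit they came from.

    ``fit_rmse`` is ``None`` until the parameters have been estimated from
    data (population/prior parameter sets have no fit error).
    """

    magnitude: float  # a, kg/day
    ramp: float       # b, days
    offset: float     # c, days
    decay: float      # 1/day
    fit_rmse: Optional[float] = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.magnitude, self.ramp, self.offset, self.decay], dtype=float
        )

    def with_rmse(self, rmse: float) -> "LactationCurveCharacteristics":
        return replace(self, fit_rmse=float(rmse))

    @property
    def persistency(self) -> float:
        """Persistency (days) implied by the decay; requires decay > 0."""
        return persistency_from_decay(self.decay)


def _validate_params(a: float, b: float, c: float, d: float) -> None:
    for name, v in (("magnitude", a), ("ramp", b), ("offset", c), ("decay", d)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite lactation-curve parameter {name}={v!r}")
    if b <= 0:
        raise ValueError(f"ramp must be positive, got {b}")


def milkbot_curve(t, a: float, b: float, c: float, d: float, clip: bool = True):
    """Evaluate the MilkBot curve on plain arrays (vectorised over ``t``).

    With ``clip=True`` (the default) negative values — possible only for
    t far below the offset — are floored at 0 kg, the physical range.
    """
    t = np.asarray(t, dtype=float)
    y = a * (1.0 - np.exp((c - t) / b) / 2.0) * np.exp(-d * t)
    if clip:
        y = np.maximum(y, 0.0)
    return y


def milk_yield(lcc: LactationCurveCharacteristics, t):
    """Estimated milk production (kg/day) at DIM ``t`` (scalar or array).

    ``t`` must be >= 0; yields are floored at 0 kg.
    """
    _validate_params(lcc.magnitude, lcc.ramp, lcc.offset, lcc.decay)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("days in milk must be >= 0")
    y = milkbot_curve(t_arr, lcc.magnitude, lcc.ramp, lcc.offset, lcc.decay)
    return float(y) if np.isscalar(t) or t_arr.ndim == 0 else y


def persistency_from_decay(d):
    """Persistency (days): half-life of milk production, ``0.693 / d``.

    Interpretable as the number of days it takes daily milk production to
    decrease by half during the declining stage of lactation.  Requires
    d > 0 (non-positive decay records are rejected upstream).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("persistency is only defined for decay > 0")
    out = HALF_LIFE_CONSTANT / d_arr
    return float(out) if d_arr.ndim == 0 else out


def decay_from_persistency(p):
    """Inverse transform: decay (1/day) from persistency (days), ``0.693 / p``."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0):
        raise ValueError("persistency must be > 0")
    out = HALF_LIFE_CONSTANT / p_arr
    return float(out) if p_arr.ndim == 0 else out


def half_life_decline(y_peak: float, p: float, elapsed) -> float:
    """Declining-phase yield after ``elapsed`` days given persistency ``p``.

    Pure half-life approximation (ramp factor treated as 1):
    ``y_peak * exp(-(0.693/p) * elapsed)``.  A cow peaking at 40 kg with a
    persistency of 300 days is back to ~20 kg 300 days later.
    """
    if p <= 0:
        raise ValueError("persistency must be > 0")
    elapsed_arr = np.asarray(elapsed, dtype=float)
    if np.any(elapsed_arr < 0):
        raise ValueError("elapsed days must be >= 0")
    out = y_peak * np.exp(-(HALF_LIFE_CONSTANT / p) * elapsed_arr)
    return float(out) if elapsed_arr.ndim == 0 else out


def m305(lcc: LactationCurveCharacteristics) -> float:
    """305-day cumulative milk production (kg): the integral of the curve.

    Closed form of the integral of the MilkBot curve over [0, 305]::

        a (1 - e^{-305 d}) / d
          + a b e^{c/b} (-1 + e^{-305 (1/b + d)}) / (2 + 2 b d)

    At d = 0 the first term takes its analytic limit ``a * 305``.
    """
    a, b, c, d = lcc.magnitude, lcc.ramp, lcc.offset, lcc.decay
    _validate_params(a, b, c, d)
    if d == 0.0:
        first = a * 305.0
    else:
        first = a * (1.0 - math.exp(-305.0 * d)) / d
    k = 1.0 / b + d
    second = a * b * math.exp(c / b) * (-1.0 + math.exp(-305.0 * k)) / (2.0 + 2.0 * b * d)
    return first + second


def peak_summary(lcc: LactationCurveCharacteristics) -> tuple[float, float]:
    """Locate the production peak: ``(peak_dim, peak_yield)``.

    Dense grid search (0.1-day step on [0, 500]) followed by local bounded
    refinement.  For d = 0 the curve is monotone non-decreasing and the
    "peak" DIM is reported as the first DIM where yield reaches 99.9% of
    the magnitude ``a``.
    """
    a, b, c, d = lcc.magnitude, lcc.ramp, lcc.offset, lcc.decay
    _validate_params(a, b, c, d)
    grid = np.arange(0.0, 500.0 + 1e-9, 0.1)
    y = milkbot_curve(grid, a, b, c, d)
    if d == 0.0:
        reached = np.nonzero(y >= 0.999 * a)[0]
        i = int(reached[0]) if reached.size else len(grid) - 1
        return float(grid[i]), float(y[i])
    i = int(np.argmax(y))
    lo = max(0.0, grid[i] - 0.5)
    hi = min(500.0, grid[i] + 0.5)
    res = minimize_scalar(
        lambda t: -milkbot_curve(t, a, b, c, d), bounds=(lo, hi), method="bounded"
    )
    t_star = float(res.x)
    y_star = float(milkbot_curve(t_star, a, b, c, d))
    if y_star < y[i]:  # refinement must never lose to the grid
        t_star, y_star = float(grid[i]), float(y[i])
    return t_star, y_star
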
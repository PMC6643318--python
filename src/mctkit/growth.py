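"""Exponential tumor-growth fitting and volume interpolation.

Subcutaneous tumor growth is well described by exponential kinetics,
``TV_d = TV_0 * exp(k d)``, which is linear after a log transform:
``ln TV_d = ln TV_0 + k d``.  Everything downstream (growth-rate ratios,
doubling/tripling times, the mixed models) builds on this log-linear view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import GrowthCurve
from .exceptions import ExtrapolationError, InsufficientDataError, UndefinedEndpointError


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear growth fit: rate ``k`` (per day), intercept, R^2, n."""

    k: float
    log_tv0: float
    r_squared: float
    n_points: int


def fit_exponential(curve: GrowthCurve) -> GrowthFit:
    """OLS fit of ln(volume) on day.

    Zero-volume points are excluded (ln 0 is undefined; complete responses are
    handled by the categorical layer).  For a constant series R^2 is reported
    as 0 by convention.
    """
    pts = [(d, v) for d, v in zip(curve.days, curve.volumes) if v > 0]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"mouse {curve.mouse_id}: need >=2 positive-volume points, have {len(pts)}"
        )
    d = np.array([p[0] for p in pts], dtype=float)
    y = np.log([p[1] for p in pts])
    dc = d - d.mean()
    yc = y - y.mean()
    sxx = float(dc @ dc)
    k = float(dc @ yc) / sxx
    intercept = float(y.mean() - k * d.mean())
    syy = float(yc @ yc)
    if syy <= 0.0:
        r2 = 0.0
    else:
        resid = yc - k * dc
        r2 = max(0.0, min(1.0, 1.0 - float(resid @ resid) / syy))
    return GrowthFit(k=k, log_tv0=intercept, r_squared=r2, n_points=len(pts))


def volume_at(curve: GrowthCurve, day: float) -> float:
    """Tumor volume at ``day``, mm^3.

    Measured days are returned exactly; off-grid days are interpolated
    linearly in ln(volume) (geometric interpolation, matching exponential
    kinetics), falling back to linear interpolation of the raw volume when a
    flanking volume is 0.
    """
    days = curve.days
    if day < days[0] or day > days[-1]:
        raise ExtrapolationError(
            f"day {day} outside measured range [{days[0]}, {days[-1]}]"
        )
    if day in days:
        return curve.volumes[days.index(day)]
    hi = next(i for i, d in enumerate(days) if d > day)
    lo = hi - 1
    d0, d1 = days[lo], days[hi]
    v0, v1 = curve.volumes[lo], curve.volumes[hi]
    frac = (day - d0) / (d1 - d0)
    if v0 > 0 and v1 > 0:
        return math.exp(math.log(v0) * (1 - frac) + math.log(v1) * frac)
    return v0 * (1 - frac) + v1 * frac


def time_to_multiple(curve: GrowthCurve, factor: float) -> dict:
    """First time the tumor reaches ``factor`` times its baseline volume.

    The crossing time between flanking measured days d1 and d2 is obtained by
    linear interpolation on the volume scale,
    ``d1 + (d2 - d1) * (factor*TV_0 - TV_1) / (TV_2 - TV_1)``,
    which for factor 2 is exactly the tumor-volume doubling-time (PFS) rule.
    Returns ``{"time": t, "event": True}`` on crossing, otherwise
    ``{"censored_at": last_day, "event": False}``.
    """
    if curve.baseline <= 0:
        raise UndefinedEndpointError(
            f"mouse {curve.mouse_id}: baseline volume must be positive"
        )
    target = factor * curve.baseline
    if curve.volumes[0] >= target:  # factor <= 1: crossed at initiation
        return {"time": 0.0, "event": True}
    for i in range(1, len(curve)):
        if curve.volumes[i] >= target:
            d1, d2 = curve.days[i - 1], curve.days[i]
            v1, v2 = curve.volumes[i - 1], curve.volumes[i]
            t = d1 + (d2 - d1) * (target - v1) / (v2 - v1)
            return {"time": float(t), "event": True}
    return {"censored_at": float(curve.last_day), "event": False}
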
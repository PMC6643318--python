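"""Continuous efficacy endpoints from matched treatment and vehicle groups.

Implemented endpoints:

* PFS — tumor-volume doubling time of a single mouse (linear interpolation
  on the volume scale between flanking measurement days);
* RTV ratio — RTV_t / RTV_c at a chosen day, group RTVs being per-mouse RTV
  aggregates;
* TGI — tumor growth inhibition, either ``1 - RTV_t/RTV_c`` or
  ``1 - mean(dT)/mean(dC)`` on raw volume changes;
* growth-rate ratio — k_t / k_c from pooled log-linear fits per arm;
* AUC ratio — area under the mean log-RTV curve per arm over a common
  window, which equals the growth-rate ratio exactly under exponential
  kinetics but remains defined for any growth shape.

RTV ratio and TGI depend on the evaluation day; growth-rate and AUC ratios
use the whole trajectory and are day-free.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .datamodel import GrowthCurve
from .exceptions import InsufficientDataError, UndefinedEndpointError
from .categorical import rtv
from .growth import fit_exponential, time_to_multiple, volume_at


def pfs(curve: GrowthCurve) -> dict:
    """Progression-free survival: tumor volume doubling time (see
    :func:`mctkit.growth.time_to_multiple` with factor 2)."""
    return time_to_multiple(curve, 2.0)


def _group_rtv(curves: Sequence[GrowthCurve], day: float, aggregate: str) -> float:
    if not curves:
        raise InsufficientDataError("empty group")
    values = [rtv(c, day) for c in curves]
    if aggregate == "mean":
        return float(np.mean(values))
    if aggregate == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def rtv_ratio(
    treated: Sequence[GrowthCurve],
    vehicle: Sequence[GrowthCurve],
    day: float,
    aggregate: str = "mean",
) -> float:
    """RTV_t / RTV_c at ``day``; group RTVs are per-mouse RTV means
    (``aggregate="median"`` switches the aggregator)."""
    rtv_c = _group_rtv(vehicle, day, aggregate)
    if rtv_c == 0:
        raise UndefinedEndpointError("vehicle group RTV is 0; RTV ratio undefined")
    return _group_rtv(treated, day, aggregate) / rtv_c


def tgi(
    treated: Sequence[GrowthCurve],
    vehicle: Sequence[GrowthCurve],
    day: float,
    variant: str = "rtv",
    aggregate: str = "mean",
) -> float:
    """Tumor growth inhibition at ``day``.

    ``variant="rtv"`` returns ``1 - RTV_t/RTV_c`` (so tgi + rtv_ratio == 1
    identically); ``variant="delta"`` returns ``1 - mean(dT)/mean(dC)`` on raw
    volume changes from baseline, which exceeds 1 for regressing tumors.
    """
    if variant == "rtv":
        return 1.0 - rtv_ratio(treated, vehicle, day, aggregate=aggregate)
    if variant == "delta":
        dT = np.mean([volume_at(c, day) - c.baseline for c in treated])
        dC = np.mean([volume_at(c, day) - c.baseline for c in vehicle])
        if dC == 0:
            raise UndefinedEndpointError("vehicle mean volume change is 0")
        return float(1.0 - dT / dC)
    raise ValueError(f"unknown TGI variant {variant!r}")


def _pooled_slope(curves: Sequence[GrowthCurve]) -> float:
    """Common growth rate across mice: OLS of log-volume on day with a free
    intercept per mouse (within-mouse estimator)."""
    num = 0.0
    den = 0.0
    for c in curves:
        pts = [(d, v) for d, v in zip(c.days, c.volumes) if v > 0]
        if len(pts) < 2:
            continue
        d = np.array([p[0] for p in pts], dtype=float)
        y = np.log([p[1] for p in pts])
        dc = d - d.mean()
        num += float(dc @ (y - y.mean()))
        den += float(dc @ dc)
    if den == 0.0:
        raise InsufficientDataError("no mouse with >=2 positive-volume points")
    return num / den


def _per_mouse_mean_slope(curves: Sequence[GrowthCurve]) -> float:
    ks = []
    for c in curves:
        try:
            ks.append(fit_exponential(c).k)
        except InsufficientDataError:
            continue
    if not ks:
        raise InsufficientDataError("no fittable mouse in group")
    return float(np.mean(ks))


def growth_rate_ratio(
    treated: Sequence[GrowthCurve],
    vehicle: Sequence[GrowthCurve],
    method: str = "pooled",
) -> float:
    """k_t / k_c from per-arm exponential fits.

    ``method="pooled"`` (default) fits a common slope with per-mouse
    intercepts; ``method="mean"`` averages per-mouse slopes.
    """
    est = {"pooled": _pooled_slope, "mean": _per_mouse_mean_slope}[method]
    k_t = est(treated)
    k_c = est(vehicle)
    if k_c == 0:
        raise UndefinedEndpointError("vehicle growth rate is 0")
    return k_t / k_c


def _mean_log_rtv_auc(curves: Sequence[GrowthCurve], grid: np.ndarray) -> float:
    logs = []
    for c in curves:
        vals = []
        for d in grid:
            v = volume_at(c, float(d))
            if v <= 0 or c.baseline <= 0:
                raise UndefinedEndpointError(
                    f"mouse {c.mouse_id}: log-RTV undefined at day {d} (zero volume)"
                )
            vals.append(math.log(v / c.baseline))
        logs.append(vals)
    mean_log = np.mean(np.array(logs), axis=0)
    return float(np.trapezoid(mean_log, grid))


def auc_ratio(
    treated: Sequence[GrowthCurve],
    vehicle: Sequence[GrowthCurve],
    end_day: Optional[float] = None,
) -> float:
    """Ratio of areas under the mean log-RTV curve, treated / vehicle.

    The window is [0, T] with T the largest day covered by every mouse in
    both groups (or ``end_day``). Under exact exponential growth each area is
    k*T^2/2 and the ratio collapses to k_t/k_c.
    """
    all_curves = list(treated) + list(vehicle)
    if not treated or not vehicle:
        raise InsufficientDataError("both groups must be non-empty")
    T = min(c.last_day for c in all_curves)
    if end_day is not None:
        T = min(T, end_day)
    if T <= 0:
        raise InsufficientDataError("no common evaluation window after day 0")
    grid = sorted({float(d) for c in all_curves for d in c.days if d <= T} | {0.0, float(T)})
    grid = np.array(grid)
    area_c = _mean_log_rtv_auc(vehicle, grid)
    if area_c == 0:
        raise UndefinedEndpointError("vehicle log-RTV area is 0")
    return _mean_log_rtv_auc(treated, grid) / area_c
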
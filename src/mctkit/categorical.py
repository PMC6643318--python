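"""Categorical efficacy endpoints: the four RTV-based response classifiers.

All four methods classify a mouse from its relative tumor volume (RTV),
volume at a later day divided by volume at treatment initiation:

* RECIST-style: CR RTV = 0, PR RTV <= 0.657, SD RTV <= 1.728, PD above;
* 3-category: OR RTV <= 0.65, PD RTV >= 1.35, SD in between;
* mRECIST: thresholds on the best response (minimum RTV over days >= 10) and
  the best average response (minimum running-mean RTV over days >= 10);
* 5-category: adds maintained CR (MCR), using the minimum RTV during the
  study and the RTV at end of study.

A model's response is the majority response of its mice; the objective
response rate is the fraction of models whose majority call is objective
(OR; CR+PR; MCR+CR+PR depending on the method).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .datamodel import CATEGORY_SETS, OBJECTIVE_SETS, GrowthCurve, MCTDataset, ResponseCall
from .exceptions import InsufficientDataError, UndefinedEndpointError, ValidationError
from .growth import volume_at

#: mRECIST (best_response, best_avg_response) upper cutoffs on the RTV scale,
#: after Gao et al.; tested in order CR, PR, SD, else PD. Configurable.
MRECIST_THRESHOLDS = {
    "CR": (0.05, 0.60),
    "PR": (0.50, 0.80),
    "SD": (1.35, 1.30),
}

#: Admissible initial tumor volume range, mm^3 (warning filter, not a failure).
ADMISSIBLE_INITIAL_VOLUME = (50.0, 300.0)

#: Tie-break order for majority calls: the most progressive category wins.
PROGRESSIVENESS = ("PD", "SD", "PR", "OR", "CR", "MCR")


def rtv(curve: GrowthCurve, day: float) -> float:
    """Relative tumor volume at ``day``: volume_at(day) / baseline."""
    if curve.baseline <= 0:
        raise UndefinedEndpointError(
            f"mouse {curve.mouse_id}: RTV undefined for zero baseline volume"
        )
    return volume_at(curve, day) / curve.baseline


def check_initial_volume(curve: GrowthCurve, bounds=ADMISSIBLE_INITIAL_VOLUME) -> bool:
    """Warn (and return False) if the baseline volume is outside the
    admissible 50-300 mm^3 enrollment range."""
    lo, hi = bounds
    if not (lo <= curve.baseline <= hi):
        warnings.warn(
            f"mouse {curve.mouse_id}: initial volume {curve.baseline:.1f} mm^3 "
            f"outside admissible range [{lo}, {hi}]",
            stacklevel=2,
        )
        return False
    return True


def _default_eval_day(curve: GrowthCurve, eval_day) -> float:
    return curve.last_day if eval_day is None else eval_day


def classify_recist(curve: GrowthCurve, eval_day: Optional[float] = None) -> str:
    """RECIST-style call from RTV at ``eval_day`` (default: last measured day)."""
    r = rtv(curve, _default_eval_day(curve, eval_day))
    if r == 0:
        return "CR"
    if r <= 0.657:
        return "PR"
    if r <= 1.728:
        return "SD"
    return "PD"


def classify_3cat(curve: GrowthCurve, eval_day: Optional[float] = None) -> str:
    """3-category call (OR / SD / PD) from RTV at ``eval_day``."""
    r = rtv(curve, _default_eval_day(curve, eval_day))
    if r <= 0.65:
        return "OR"
    if r >= 1.35:
        return "PD"
    return "SD"


@dataclass(frozen=True)
class MrecistSummary:
    """The two mRECIST summaries (minima taken over measured days >= 10)."""

    best_response: float
    best_avg_response: float


def mrecist_summary(curve: GrowthCurve, window_start: float = 10.0) -> MrecistSummary:
    """Best response and best average response.

    best_response is the minimum RTV over measured days >= ``window_start``;
    best_avg_response is the minimum over those days t of the mean RTV from
    day 0 through t (the running average, so early growth keeps weighing in).
    """
    rtvs = [rtv(curve, d) for d in curve.days]
    late = [i for i, d in enumerate(curve.days) if d >= window_start]
    if not late:
        raise InsufficientDataError(
            f"mouse {curve.mouse_id}: no measurement at day >= {window_start}"
        )
    best = min(rtvs[i] for i in late)
    running = [sum(rtvs[: i + 1]) / (i + 1) for i in late]
    return MrecistSummary(best_response=best, best_avg_response=min(running))


def classify_mrecist(
    curve: GrowthCurve,
    thresholds: Mapping[str, tuple] = MRECIST_THRESHOLDS,
    window_start: float = 10.0,
) -> str:
    """mRECIST call: categories tested in order CR, PR, SD, else PD."""
    s = mrecist_summary(curve, window_start=window_start)
    for cat in ("CR", "PR", "SD"):
        br_max, bar_max = thresholds[cat]
        if s.best_response < br_max and s.best_avg_response < bar_max:
            return cat
    return "PD"


def classify_5cat(curve: GrowthCurve, eval_day: Optional[float] = None) -> str:
    """5-category call (MCR/CR/PR/SD/PD), tested in that order.

    MCR: RTV = 0 at end of study; CR: RTV = 0 at >= 1 time point;
    PR: RTV <= 0.50 at >= 1 time point (after day 0); SD: end RTV <= 1.25;
    PD otherwise.
    """
    end_day = _default_eval_day(curve, eval_day)
    rtvs = [rtv(curve, d) for d in curve.days if d <= end_day]
    end_rtv = rtv(curve, end_day)
    if end_rtv == 0:
        return "MCR"
    if any(r == 0 for r in rtvs):
        return "CR"
    # day 0 has RTV 1 and cannot trigger PR; minimum over later days
    later = [r for r, d in zip(rtvs, curve.days) if 0 < d <= end_day]
    if later and min(later) <= 0.50:
        return "PR"
    if end_rtv <= 1.25:
        return "SD"
    return "PD"


_CLASSIFIERS = {
    "recist": classify_recist,
    "cat3": classify_3cat,
    "mrecist": lambda curve, eval_day=None: classify_mrecist(curve),
    "cat5": classify_5cat,
}


def classify(curve: GrowthCurve, method: str, eval_day: Optional[float] = None) -> ResponseCall:
    """Classify one mouse with the named method, returning a ResponseCall."""
    if method not in _CLASSIFIERS:
        raise ValidationError(f"unknown method {method!r}")
    cat = _CLASSIFIERS[method](curve, eval_day=eval_day)
    return ResponseCall(
        method=method, category=cat, mouse_id=curve.mouse_id, model_id=curve.model_id
    )


def majority_response(calls: Sequence[ResponseCall]) -> str:
    """Modal category of a group of same-method calls.

    Ties break toward the more progressive category (PD > SD > PR/OR > CR >
    MCR), a conservative efficacy convention.
    """
    if not calls:
        raise ValidationError("majority_response needs at least one call")
    methods = {c.method for c in calls}
    if len(methods) > 1:
        raise ValidationError(f"mixed methods in majority_response: {sorted(methods)}")
    counts = Counter(c.category for c in calls)
    top = max(counts.values())
    tied = [cat for cat, n in counts.items() if n == top]
    return min(tied, key=PROGRESSIVENESS.index)


def classify_dataset(
    dataset: MCTDataset,
    method: str,
    arm: str = "treatment",
    eval_day: Optional[float] = None,
) -> pd.DataFrame:
    """Per-mouse calls plus per-model majority for one arm of a dataset.

    When ``eval_day`` is None each model is evaluated at its mice's last
    common measured day.  Returns a tidy DataFrame with columns
    model_id, mouse_id, method, category, majority.
    """
    rows = []
    for model_id in dataset.model_ids:
        curves = dataset.curves_for(model_id, arm=arm)
        if not curves:
            continue
        day = eval_day
        if day is None:
            day = min(c.last_day for c in curves)
        calls = [classify(c, method, eval_day=day) for c in curves]
        maj = majority_response(calls)
        for call in calls:
            rows.append((model_id, call.mouse_id, method, call.category, maj))
    return pd.DataFrame(
        rows, columns=["model_id", "mouse_id", "method", "category", "majority"]
    )


def objective_response_rate(model_calls: Mapping[str, str], method: str) -> float:
    """Fraction of models whose (majority) category is an objective response."""
    if method not in OBJECTIVE_SETS:
        raise ValidationError(f"unknown method {method!r}")
    if not model_calls:
        raise ValidationError("objective_response_rate needs at least one model")
    valid = CATEGORY_SETS[method]
    for m, cat in model_calls.items():
        if cat not in valid:
            raise ValidationError(f"category {cat!r} invalid for method {method!r}")
    objective = OBJECTIVE_SETS[method]
    hits = sum(1 for cat in model_calls.values() if cat in objective)
    return hits / len(model_calls)
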
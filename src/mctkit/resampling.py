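"""Subsampling procedures relating mouse number to measurement accuracy.

For categorical endpoints: repeatedly draw n mice from a model's treated
group, take the majority response, and score agreement with the full-group
majority; accuracy is summarized per actual-majority category and as the
unweighted mean across categories.  For continuous endpoints: recompute the
endpoint on each subsample and record its error against the all-mice value,
yielding an empirical CDF of errors per n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MCTDataset
from .exceptions import InsufficientDataError, UndefinedEndpointError, ValidationError
from .categorical import CATEGORY_SETS, classify, majority_response
from .continuous import pfs, rtv_ratio
from .growth import time_to_multiple


@dataclass
class AccuracyCurve:
    """Subsampling accuracy per subsample size n.

    ``per_category_accuracy[cat]`` maps each n to (mean, sd) across models
    whose actual majority is ``cat``; ``unweighted_mean_accuracy`` averages
    the category means without weighting by category frequency.
    """

    method: str
    n_values: list
    per_category_accuracy: Dict[str, Dict[int, tuple]]
    unweighted_mean_accuracy: Dict[int, float]
    replications: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, by_n in self.per_category_accuracy.items():
            for n, (mean, sd) in by_n.items():
                rows.append(
                    {"category": cat, "n": n, "accuracy_mean": mean, "accuracy_sd": sd}
                )
        return pd.DataFrame(rows)


def categorical_accuracy(
    dataset: MCTDataset,
    method: str,
    n_values: Sequence[int] = (1, 3, 5, 7),
    replications: int = 1000,
    seed=None,
    arm: str = "treatment",
    eval_day: Optional[float] = None,
    with_replacement: bool = False,
) -> AccuracyCurve:
    """Accuracy of the majority response from n subsampled mice.

    Sampling is without replacement by default.  Every model must have at
    least max(n_values) mice in ``arm``.  Subsample majorities use the same
    progressive tie-break as the full-group majority, so accuracy is exactly
    1 when n equals the group size.
    """
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    n_values = sorted(int(n) for n in n_values)

    model_calls = {}
    for model_id in dataset.model_ids:
        curves = dataset.curves_for(model_id, arm=arm)
        if not curves:
            continue
        day = eval_day if eval_day is not None else min(c.last_day for c in curves)
        calls = [classify(c, method, eval_day=day) for c in curves]
        if len(calls) < max(n_values) and not with_replacement:
            raise InsufficientDataError(
                f"model {model_id}: {len(calls)} mice < max n {max(n_values)}"
            )
        model_calls[model_id] = calls

    agree = {
        cat: {n: [] for n in n_values} for cat in CATEGORY_SETS[method]
    }
    for model_id, calls in model_calls.items():
        truth = majority_response(calls)
        for n in n_values:
            hits = 0
            for _ in range(replications):
                idx = (
                    rng.integers(0, len(calls), size=n)
                    if with_replacement
                    else rng.choice(len(calls), size=n, replace=False)
                )
                sub = [calls[i] for i in idx]
                if majority_response(sub) == truth:
                    hits += 1
            agree[truth][n].append(hits / replications)

    per_cat = {}
    for cat, by_n in agree.items():
        if not any(by_n.values()):
            continue
        per_cat[cat] = {
            n: (float(np.mean(v)), float(np.std(v, ddof=0))) for n, v in by_n.items()
        }
    unweighted = {
        n: float(np.mean([per_cat[cat][n][0] for cat in per_cat]))
        for n in n_values
    }
    return AccuracyCurve(
        method=method,
        n_values=list(n_values),
        per_category_accuracy=per_cat,
        unweighted_mean_accuracy=unweighted,
        replications=replications,
    )


def _group_pfs(curves) -> float:
    """Group-level PFS: median per-mouse doubling time (censored times enter
    at their censoring value)."""
    times = []
    for c in curves:
        res = time_to_multiple(c, 2.0)
        times.append(res["time"] if res["event"] else res["censored_at"])
    return float(np.median(times))


def continuous_error(
    dataset: MCTDataset,
    endpoint: str = "pfs",
    n_values: Sequence[int] = tuple(range(1, 10)),
    replications: int = 1000,
    seed=None,
    error_type: str = "percent",
    min_group: int = 10,
    eval_day: Optional[float] = None,
) -> pd.DataFrame:
    """Subsampling error distribution for a continuous endpoint.

    ``endpoint`` is "pfs" (treated arm only; group value = median doubling
    time) or "rtv_ratio" (n mice drawn from each arm).  Only models with at
    least ``min_group`` mice per relevant arm enter (the >= 10-mice inclusion
    rule).  Returns a tidy frame with one row per model x n x replication:
    columns model_id, n, rep, error (NaN when the endpoint was undefined on
    the subsample; the missing rate is recoverable as the NaN fraction).
    Errors are |sub - full| / full * 100 for "percent", |sub - full| for
    "absolute".
    """
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    if endpoint not in ("pfs", "rtv_ratio"):
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for model_id in dataset.model_ids:
        treated = dataset.curves_for(model_id, "treatment")
        vehicle = dataset.curves_for(model_id, "vehicle")
        if endpoint == "pfs":
            if len(treated) < min_group:
                continue
            full = _group_pfs(treated)
        else:
            if len(treated) < min_group or len(vehicle) < min_group:
                continue
            day = eval_day
            if day is None:
                day = min(c.last_day for c in treated + vehicle)
            full = rtv_ratio(treated, vehicle, day)
        for n in n_values:
            for rep in range(replications):
                try:
                    if endpoint == "pfs":
                        idx = rng.choice(len(treated), size=n, replace=False)
                        sub = _group_pfs([treated[i] for i in idx])
                    else:
                        it = rng.choice(len(treated), size=n, replace=False)
                        iv = rng.choice(len(vehicle), size=n, replace=False)
                        sub = rtv_ratio(
                            [treated[i] for i in it], [vehicle[i] for i in iv], day
                        )
                    if error_type == "percent":
                        err = abs(sub - full) / abs(full) * 100.0
                    else:
                        err = abs(sub - full)
                except (UndefinedEndpointError, InsufficientDataError):
                    err = np.nan
                rows.append((model_id, int(n), rep, err))
    if not rows:
        raise InsufficientDataError(
            f"no model satisfies the >= {min_group}-mice inclusion rule"
        )
    return pd.DataFrame(rows, columns=["model_id", "n", "rep", "error"])


def error_ecdf(errors: pd.DataFrame, n: int, at: float) -> float:
    """Empirical CDF of the pooled error distribution at threshold ``at``
    for subsample size ``n`` (NaN replications count in the denominator)."""
    sub = errors[errors["n"] == n]["error"]
    if sub.empty:
        raise ValidationError(f"no errors recorded for n={n}")
    return float((sub <= at).sum() / len(sub))
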
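"""Simulation-based statistical power for n:n MCT designs.

A design is (G models) x (n mice per model per arm).  For the longitudinal
engine, trials are simulated from the three-level growth model with a
treatment effect beta2 = ratio * beta1 (ratio = -0.2 means a 20% growth-rate
reduction) and analyzed by REML with a two-sided Wald test on the
Day:Treatment term.  For the survival engine, clustered event times are
simulated from the additive frailty model at a given hazard ratio and
analyzed by the frailty fitter with a Wald test on w.  Power is the
rejection fraction; failed fits count as non-rejections (conservative) and
the failure rate is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, InsufficientDataError, MCTError
from .lmm import LMMSpec, fit_lmm
from .simulate import SimConfig, generate_mct, generate_survival
from .survival import fit_frailty


@dataclass
class PowerCell:
    n_models: int
    n_mice: int
    effect: float  # beta2/beta1 ratio, or hazard ratio
    power: float
    ci_low: float
    ci_high: float
    replications: int
    failure_rate: float


def _binomial_ci(k: int, n: int) -> tuple:
    p = k / n
    half = 1.959964 * math.sqrt(max(p * (1 - p), 1e-12) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _to_frame(cells) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def power_lmm(
    n_models: Sequence[int] = (10, 20, 40),
    n_mice: Sequence[int] = (1, 3),
    effect_ratios: Sequence[float] = (-0.1, -0.2, -0.3),
    replications: int = 500,
    alpha: float = 0.05,
    seed=None,
    base_config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Power grid for the longitudinal engine.

    Returns a tidy frame with one row per (G, n, effect ratio) cell:
    power with a 95% Monte-Carlo binomial CI and the fit-failure rate.
    Cells with failure rate > 5% should be treated as unreliable (flagged by
    the ``failure_rate`` column).
    """
    if seed is None:
        raise MCTError("seed is required")
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    cells = []
    for G in n_models:
        for n in n_mice:
            for ratio in effect_ratios:
                cfg = replace(base.with_effect_ratio(ratio), n_models=G, n_mice_per_arm=n)
                rej = 0
                failures = 0
                theta0 = None
                for _ in range(replications):
                    s = int(rng.integers(0, 2**31 - 1))
                    try:
                        ds, _ = generate_mct(cfg, seed=s)
                        fit = fit_lmm(ds, LMMSpec(), theta0=theta0)
                        theta0 = fit.theta
                        if fit.pvalue("Day:Treatment") < alpha:
                            rej += 1
                    except (ConvergenceError, InsufficientDataError):
                        failures += 1  # counted as non-rejection
                lo, hi = _binomial_ci(rej, replications)
                cells.append(
                    PowerCell(G, n, ratio, rej / replications, lo, hi,
                              replications, failures / replications)
                )
    return _to_frame(cells)


def power_frailty(
    n_models: Sequence[int] = (10, 20, 30),
    n_mice: Sequence[int] = (1, 3),
    hazard_ratios: Sequence[float] = (0.7, 0.5, 0.3),
    replications: int = 200,
    alpha: float = 0.05,
    seed=None,
    base_config: Optional[SimConfig] = None,
    fix_rho: Optional[float] = 0.0,
    n_quad: int = 7,
) -> pd.DataFrame:
    """Power grid for the survival engine (additive frailty analysis of
    clustered event times simulated at each hazard ratio)."""
    if seed is None:
        raise MCTError("seed is required")
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    cells = []
    for G in n_models:
        for n in n_mice:
            for hr in hazard_ratios:
                cfg = replace(
                    base, n_models=G, n_mice_per_arm=n, log_hr=math.log(hr)
                )
                rej = 0
                failures = 0
                for _ in range(replications):
                    s = int(rng.integers(0, 2**31 - 1))
                    try:
                        recs, _ = generate_survival(cfg, seed=s)
                        fit = fit_frailty(recs, fix_rho=fix_rho, n_quad=n_quad)
                        if fit.p_w < alpha:
                            rej += 1
                    except (ConvergenceError, InsufficientDataError):
                        failures += 1
                lo, hi = _binomial_ci(rej, replications)
                cells.append(
                    PowerCell(G, n, hr, rej / replications, lo, hi,
                              replications, failures / replications)
                )
    return _to_frame(cells)


def plot_power_curves(grid: pd.DataFrame, ax=None):
    """Power vs effect, one line per (G, n) design (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (G, n), sub in grid.groupby(["n_models", "n_mice"]):
        sub = sub.sort_values("effect")
        ax.plot(sub["effect"], sub["power"], marker="o", label=f"{G} models, {n}:{n}")
    ax.set_xlabel("effect (growth-rate ratio or hazard ratio)")
    ax.set_ylabel("power")
    ax.axhline(0.8, ls="--", lw=0.5, color="gray")
    ax.legend(fontsize=8)
    return ax
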
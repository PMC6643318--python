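"""Synthetic mouse-clinical-trial generator with known ground truth.

The generator draws clustered longitudinal log-volumes from the same
three-level structure the mixed models assume:

    log TV_tij = b0 + b1*Day + b2*Day*Treat [+ gene terms]
                 + u0j + u1j*Day            (model level)
                 + u0i|j + u1i|j*Day        (mouse-within-model level)
                 + eps_tij

with multivariate-normal random effects, iid normal residuals, log-uniform
initial volumes in the dosing-start range 100-300 mm^3, twice-weekly
measurement over a 21-day trial, and euthanasia-driven truncation once a
mouse's volume reaches 3000 mm^3.  Clustered survival data are drawn from the
additive frailty hazard h0(t)*exp(u_i + (w + v_i)*T) with a Weibull baseline.
Every latent draw is retained in a truth record so estimators can be checked
for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import GrowthCurve, MCTDataset
from .exceptions import ValidationError

#: Twice-weekly measurement over a 21-day trial: 8 points per mouse.
DEFAULT_SCHEDULE = (0, 3, 6, 9, 12, 15, 18, 21)


def _cov2(sd_intercept: float, sd_slope: float, corr: float) -> np.ndarray:
    c = corr * sd_intercept * sd_slope
    return np.array([[sd_intercept**2, c], [c, sd_slope**2]])


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the reference synthetic trial.

    Defaults are a documented "cisplatin-like" preset: baseline volume about
    150 mm^3 growing at 0.06/day, a treatment that multiplies the growth rate
    by ``1 + effect_ratio`` (so effect_ratio = -0.2 is a 20% growth-rate
    reduction), and variance components sized so that a 1:1 design with
    ~36 models reaches ~90% power at a 20% reduction.
    """

    n_models: int = 20
    n_mice_per_arm: int = 3
    schedule: Sequence[int] = DEFAULT_SCHEDULE
    beta0: float = math.log(150.0)
    beta1: float = 0.06  # vehicle growth rate, per day
    beta2: float = -0.012  # treatment effect on the growth rate, per day
    model_sd_intercept: float = 0.25
    model_sd_slope: float = 0.015
    model_corr: float = 0.0
    mouse_sd_intercept: float = 0.10
    mouse_sd_slope: float = 0.014
    mouse_corr: float = 0.0
    residual_sd: float = 0.12
    initial_volume_range: tuple = (100.0, 300.0)
    dropout_threshold: float = 3000.0
    # expression block (planted biomarker); zero by default so the base
    # generator is exactly the three-level model with no covariates
    n_genes: int = 500
    gene_growth_effect: float = 0.0  # per SD of expression, on the Day slope
    gene_treatment_effect: float = 0.0  # per SD, on the Day x Treat slope
    # survival block (additive frailty world)
    weibull_shape: float = 2.0
    weibull_scale: float = 12.0
    frailty_sigma2: float = 0.5
    frailty_tau2: float = 0.2
    frailty_rho: float = 0.0
    log_hr: float = math.log(0.5)
    censor_horizon: float = 60.0

    @property
    def model_cov(self) -> np.ndarray:
        return _cov2(self.model_sd_intercept, self.model_sd_slope, self.model_corr)

    @property
    def mouse_cov(self) -> np.ndarray:
        return _cov2(self.mouse_sd_intercept, self.mouse_sd_slope, self.mouse_corr)

    def with_effect_ratio(self, ratio: float) -> "SimConfig":
        """Copy with beta2 = ratio * beta1 (ratio -0.2 = 20% reduction)."""
        return replace(self, beta2=ratio * self.beta1)


def cisplatin_like() -> SimConfig:
    """The reference preset (see class docstring)."""
    return SimConfig()


def biomarker_preset(n_genes: int = 500) -> SimConfig:
    """Reference planted-biomarker world: one causal gene whose standardized
    expression slows untreated growth (-0.02/day per SD) and shrinks the
    treatment benefit (+0.02/day per SD) — comparable magnitudes, opposite
    signs, the prognostic-vs-predictive pattern."""
    return replace(
        SimConfig(),
        n_genes=n_genes,
        gene_growth_effect=-0.02,
        gene_treatment_effect=0.02,
    )


def _check_cov(cov: np.ndarray, what: str):
    if not np.all(np.linalg.eigvalsh(cov) >= -1e-12):
        raise ValidationError(f"{what} covariance is not positive semi-definite")


def generate_mct(config: SimConfig, seed) -> tuple:
    """Simulate one trial; returns ``(MCTDataset, truth)``.

    ``truth`` retains the fixed effects and every latent random-effect draw
    (per model and per mouse), plus per-model gene values when expression
    effects are active via :func:`generate_expression`.
    """
    _check_cov(config.model_cov, "model-level")
    _check_cov(config.mouse_cov, "mouse-level")
    if config.dropout_threshold <= config.initial_volume_range[1]:
        raise ValidationError("dropout threshold must exceed the max initial volume")
    rng = np.random.default_rng(seed)
    days = np.asarray(config.schedule, dtype=float)

    # per-model standardized gene value driving the planted-biomarker effects;
    # generate_expression embeds it in the expression matrix.
    gene = rng.standard_normal(config.n_models)
    gene = (gene - gene.mean()) / gene.std(ddof=0)

    curves = []
    covariates = {}
    truth = {
        "config": config,
        "gene_value": {},
        "model_effects": {},
        "mouse_effects": {},
    }
    use_gene = config.gene_growth_effect != 0 or config.gene_treatment_effect != 0
    for j in range(config.n_models):
        model_id = f"M{j:03d}"
        covariates[model_id] = {"cancer_type": "NA"}
        u_model = rng.multivariate_normal(np.zeros(2), config.model_cov)
        truth["model_effects"][model_id] = tuple(u_model)
        truth["gene_value"][model_id] = gene[j]
        g = gene[j]
        for arm, treat in (("vehicle", 0), ("treatment", 1)):
            for i in range(config.n_mice_per_arm):
                mouse_id = f"{model_id}_{arm[0]}{i}"
                u_mouse = rng.multivariate_normal(np.zeros(2), config.mouse_cov)
                truth["mouse_effects"][(model_id, mouse_id)] = tuple(u_mouse)
                tv0 = math.exp(
                    rng.uniform(
                        math.log(config.initial_volume_range[0]),
                        math.log(config.initial_volume_range[1]),
                    )
                )
                slope = (
                    config.beta1
                    + config.beta2 * treat
                    + u_model[1]
                    + u_mouse[1]
                )
                if use_gene:
                    slope += config.gene_growth_effect * g
                    slope += config.gene_treatment_effect * g * treat
                # tv0 replaces beta0 + intercept effects: the intercept random
                # effects act through the log-uniform baseline draw instead, so
                # log TV = log tv0 + intercept noise + slope*day + residual.
                log_tv = (
                    math.log(tv0)
                    + u_model[0]
                    + u_mouse[0]
                    + slope * days
                    + config.residual_sd * rng.standard_normal(len(days))
                )
                volumes = np.exp(log_tv)
                # baseline measurement is the day-0 value as generated
                keep = len(days)
                over = np.nonzero(volumes >= config.dropout_threshold)[0]
                if over.size:
                    keep = max(2, int(over[0]) + 1)  # final >=threshold point kept
                curves.append(
                    GrowthCurve(
                        mouse_id=mouse_id,
                        model_id=model_id,
                        arm=arm,
                        days=tuple(int(d) for d in days[:keep]),
                        volumes=tuple(volumes[:keep]),
                    )
                )
    dataset = MCTDataset(curves=curves, model_covariates=covariates)
    return dataset, truth


def generate_expression(config: SimConfig, truth: dict, seed) -> pd.DataFrame:
    """Expression matrix (gene x model) with one causal gene.

    Gene 0 ("G_causal") carries exactly the standardized per-model value that
    drove the growth/treatment slopes in :func:`generate_mct`; the remaining
    ``n_genes - 1`` genes are iid standard normal noise.  Truth gains the
    causal identity and effect sizes.
    """
    rng = np.random.default_rng(seed)
    models = sorted(truth["gene_value"])
    causal = np.array([truth["gene_value"][m] for m in models])
    noise = rng.standard_normal((config.n_genes - 1, len(models)))
    data = np.vstack([causal, noise])
    index = ["G_causal"] + [f"G{i:04d}" for i in range(1, config.n_genes)]
    truth["causal_gene"] = "G_causal"
    truth["causal_effects"] = {
        "growth": config.gene_growth_effect,
        "treatment": config.gene_treatment_effect,
    }
    return pd.DataFrame(data, index=index, columns=models)


def generate_survival(config: SimConfig, seed) -> tuple:
    """Clustered survival data from the additive frailty model.

    Event times are drawn by inverse transform from the conditional Weibull
    hazard ``h0(t) exp(u_i + (w + v_i) T)`` with ``H0(t) = (t/scale)^shape``;
    times beyond ``censor_horizon`` are administratively censored.  Returns
    ``(records, truth)`` where records is the list of
    :class:`mctkit.survival.SurvivalRecord`.
    """
    from .survival import SurvivalRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    s, t2, rho = config.frailty_sigma2, config.frailty_tau2, config.frailty_rho
    cov = np.array(
        [[s, rho * math.sqrt(s * t2)], [rho * math.sqrt(s * t2), t2]]
    )
    _check_cov(cov, "frailty")
    records = []
    truth = {"config": config, "frailties": {}}
    for j in range(config.n_models):
        model_id = f"M{j:03d}"
        u, v = rng.multivariate_normal(np.zeros(2), cov)
        truth["frailties"][model_id] = (u, v)
        for arm, treat in (("vehicle", 0), ("treatment", 1)):
            for i in range(config.n_mice_per_arm):
                eta = u + (config.log_hr + v) * treat
                e = rng.exponential()
                t = config.weibull_scale * (e * math.exp(-eta)) ** (
                    1.0 / config.weibull_shape
                )
                event = t <= config.censor_horizon
                records.append(
                    SurvivalRecord(
                        model_id=model_id,
                        mouse_id=f"{model_id}_{arm[0]}{i}",
                        treatment=treat,
                        time=float(min(t, config.censor_horizon))
                        if config.censor_horizon > 0
                        else float(np.finfo(float).tiny),
                        event=bool(event) if config.censor_horizon > 0 else False,
                        covariates=(),
                    )
                )
    return records, truth
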
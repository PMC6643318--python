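"""Three-level linear mixed models for MCTs as clustered longitudinal studies.

The response is log tumor volume; time enters through the Day slope, and
every fixed covariate acts on the slope (growth is what treatment and
biology modify under exponential kinetics).  The general fixed structure is

    log TV = b0 + b1*Day + sum_c Day*c + [Day*Treatment]
             + [sum_c Day*c*Treatment] + random effects + eps

with random intercept+slope at the model level and at the mouse-within-model
level (unstructured 2x2 covariance each), estimated by REML.  Inference on
fixed effects uses large-sample Wald z tests.

The same machinery powers single-gene biomarker scanning: the gene value
(standardized across models) enters as a slope covariate and as a
slope-by-treatment interaction; the Day x Gene x Treatment coefficient is
the predictive-biomarker effect.  A naive per-gene Spearman correlation
against TGI is provided as the false-positive-prone comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._reml import REMLResult, fit_reml
from .datamodel import MCTDataset
from .exceptions import InsufficientDataError, ValidationError
from .continuous import tgi

__all__ = [
    "LMMSpec",
    "LMMFit",
    "fit_lmm",
    "biomarker_scan",
    "naive_correlation_scan",
    "interpret_gene_effects",
]


@dataclass(frozen=True)
class LMMSpec:
    """Fixed-effect structure of the model.

    ``model_covariates`` lists model-level covariate names (from the
    dataset's covariate table, or a gene passed explicitly); categorical
    covariates expand to dummies against ``reference_level``; numeric ones
    enter as given (standardize upstream if comparability matters).
    """

    model_covariates: tuple = ()
    include_treatment: bool = True
    include_covariate_by_treatment: bool = False
    reference_level: Optional[str] = None


@dataclass
class LMMFit:
    """REML fit: fixed effects with Wald tests, per-level random-effect
    covariances, residual SD, and bookkeeping."""

    fixed_effects: Dict[str, tuple]  # name -> (estimate, se, p)
    random_effect_cov: Dict[str, np.ndarray]  # "model" / "mouse" -> 2x2
    residual_sd: float
    log_likelihood: float
    n_models: int
    n_mice: int
    n_observations: int
    converged: bool
    n_zero_volume_dropped: int = 0
    theta: Optional[np.ndarray] = None  # internal warm-start state

    def coef(self, name: str) -> float:
        return self.fixed_effects[name][0]

    def se(self, name: str) -> float:
        return self.fixed_effects[name][1]

    def pvalue(self, name: str) -> float:
        return self.fixed_effects[name][2]

    def wald_ci(self, name: str, level: float = 0.95) -> tuple:
        est, se, _ = self.fixed_effects[name]
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (est - z * se, est + z * se)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": k, "estimate": v[0], "se": v[1], "p_value": v[2]}
            for k, v in self.fixed_effects.items()
        ]
        return pd.DataFrame(rows).set_index("term")


def _covariate_columns(dataset: MCTDataset, spec: LMMSpec, extra: Mapping = None):
    """Resolve model-level covariates to (name, {model_id: value}) pairs."""
    extra = extra or {}
    out = []
    for name in spec.model_covariates:
        if name in extra:
            vals = {m: float(extra[name][m]) for m in dataset.model_ids}
            out.append((name, vals))
            continue
        raw = {m: dataset.model_covariates[m].get(name) for m in dataset.model_ids}
        if any(v is None for v in raw.values()):
            raise ValidationError(f"covariate {name!r} missing for some models")
        if all(isinstance(v, (int, float, np.floating, np.integer)) for v in raw.values()):
            out.append((name, {m: float(v) for m, v in raw.items()}))
        else:
            levels = sorted({str(v) for v in raw.values()})
            ref = spec.reference_level or levels[0]
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} not among {levels}")
            for lev in levels:
                if lev == ref:
                    continue
                out.append(
                    (f"{name}[{lev}]", {m: float(str(v) == lev) for m, v in raw.items()})
                )
    return out


def _design(dataset: MCTDataset, spec: LMMSpec, extra_covariates=None):
    covs = _covariate_columns(dataset, spec, extra_covariates)
    names = ["Intercept", "Day"]
    names += [f"Day:{c}" for c, _ in covs]
    if spec.include_treatment:
        names.append("Day:Treatment")
    if spec.include_covariate_by_treatment:
        names += [f"Day:{c}:Treatment" for c, _ in covs]

    rows_X, rows_y, rows_day, mouse_of_obs, model_of_mouse = [], [], [], [], []
    model_index = {m: j for j, m in enumerate(dataset.model_ids)}
    n_zero = 0
    mouse_counter = 0
    for curve in dataset.curves:
        treat = 1.0 if curve.arm == "treatment" else 0.0
        cvals = [vals[curve.model_id] for _, vals in covs]
        pts = [(d, v) for d, v in zip(curve.days, curve.volumes) if v > 0]
        n_zero += len(curve) - len(pts)
        if len(pts) < 2:
            warnings.warn(
                f"mouse {curve.mouse_id}: <2 positive-volume observations, dropped",
                stacklevel=2,
            )
            continue
        for d, v in pts:
            row = [1.0, float(d)]
            row += [float(d) * c for c in cvals]
            if spec.include_treatment:
                row.append(float(d) * treat)
            if spec.include_covariate_by_treatment:
                row += [float(d) * c * treat for c in cvals]
            rows_X.append(row)
            rows_y.append(np.log(v))
            rows_day.append(float(d))
            mouse_of_obs.append(mouse_counter)
        model_of_mouse.append(model_index[curve.model_id])
        mouse_counter += 1
    if mouse_counter == 0:
        raise InsufficientDataError("no mouse with >=2 positive-volume observations")
    return (
        np.asarray(rows_X),
        np.asarray(rows_y),
        np.asarray(rows_day),
        np.asarray(mouse_of_obs),
        np.asarray(model_of_mouse),
        names,
        n_zero,
    )


def fit_lmm(
    dataset: MCTDataset,
    spec: LMMSpec = LMMSpec(),
    extra_covariates: Optional[Mapping] = None,
    theta0: Optional[np.ndarray] = None,
) -> LMMFit:
    """REML fit of the specified three-level model to log tumor volumes.

    Zero-volume observations are dropped (with a count retained on the fit);
    ``extra_covariates`` supplies covariates not in the dataset's table, e.g.
    ``{"Gene": {model_id: value}}``. ``theta0`` warm-starts the variance
    parameters (used by the genome scan).
    """
    X, y, day, mouse_of_obs, model_of_mouse, names, n_zero = _design(
        dataset, spec, extra_covariates
    )
    res = fit_reml(X, y, day, mouse_of_obs, model_of_mouse, theta0=theta0)
    se = np.sqrt(np.diag(res.cov_beta))
    z = res.beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fixed = {
        name: (float(b), float(s), float(max(p, np.finfo(float).tiny)))
        for name, b, s, p in zip(names, res.beta, se, pvals)
    }
    return LMMFit(
        fixed_effects=fixed,
        random_effect_cov={"model": res.G, "mouse": res.H},
        residual_sd=float(np.sqrt(res.sigma2)),
        log_likelihood=res.loglik,
        n_models=int(np.max(model_of_mouse)) + 1,
        n_mice=len(model_of_mouse),
        n_observations=res.n_obs,
        converged=res.converged,
        n_zero_volume_dropped=n_zero,
        theta=res.theta,
    )


def biomarker_scan(
    dataset: MCTDataset,
    expression: Optional[pd.DataFrame] = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Single-gene biomarker scan.

    For each gene, fits the model with the gene value as a slope covariate
    and slope-by-treatment interaction, and reports the Day:Gene:Treatment
    coefficient (the predictive effect) with its Wald p-value. Returns a
    DataFrame indexed by gene with columns beta4, se, p_value, rank (1 = most
    significant) and BH-adjusted p_adj.  Constant genes are skipped and
    flagged with NaN.  Genes are standardized across models by default.
    """
    if expression is None:
        expression = dataset.expression
    if expression is None:
        raise ValidationError("no expression matrix available")
    spec = LMMSpec(
        model_covariates=("Gene",),
        include_treatment=True,
        include_covariate_by_treatment=True,
    )
    models = dataset.model_ids
    theta0 = None
    try:
        base = fit_lmm(dataset, LMMSpec())
        theta0 = base.theta
    except Exception:
        pass

    rows = []
    for gene in expression.index:
        vals = expression.loc[gene, models].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            rows.append({"gene": gene, "beta4": np.nan, "se": np.nan,
                         "p_value": np.nan, "skipped": True})
            continue
        if standardize:
            vals = (vals - vals.mean()) / sd
        gv = dict(zip(models, vals))
        try:
            fit = fit_lmm(
                dataset, spec, extra_covariates={"Gene": gv}, theta0=theta0
            )
            theta0 = fit.theta
            est, se, p = fit.fixed_effects["Day:Gene:Treatment"]
            rows.append({"gene": gene, "beta4": est, "se": se,
                         "p_value": p, "skipped": False})
        except (InsufficientDataError,) as exc:
            rows.append({"gene": gene, "beta4": np.nan, "se": np.nan,
                         "p_value": np.nan, "skipped": True})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p_value"].notna()
    out["rank"] = np.nan
    out.loc[ok, "rank"] = out.loc[ok, "p_value"].rank(method="min")
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value")


def naive_correlation_scan(
    expression: pd.DataFrame, tgi_by_model: Mapping[str, float]
) -> pd.DataFrame:
    """Per-gene Spearman correlation between expression and per-model TGI.

    The simple comparator: rank by |rho| descending.  Needs >= 3 models.
    Constant genes get NaN correlation and no rank.
    """
    models = [m for m in expression.columns if m in tgi_by_model]
    if len(models) < 3:
        raise InsufficientDataError("naive scan needs >= 3 models with TGI values")
    t = np.array([tgi_by_model[m] for m in models], dtype=float)
    rows = []
    for gene in expression.index:
        vals = expression.loc[gene, models].to_numpy(dtype=float)
        if vals.std(ddof=0) == 0 or np.std(t) == 0:
            rows.append({"gene": gene, "rho": np.nan})
            continue
        rho = stats.spearmanr(vals, t).statistic
        rows.append({"gene": gene, "rho": float(rho)})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["rho"].notna()
    out["rank"] = np.nan
    out.loc[ok, "rank"] = (-out.loc[ok, "rho"].abs()).rank(method="min")
    return out.sort_values("rank")


def tgi_by_model(dataset: MCTDataset, day: Optional[float] = None) -> Dict[str, float]:
    """Per-model TGI (1 - RTV_t/RTV_c) at ``day`` (default: the model's last
    common measured day), for use with :func:`naive_correlation_scan`."""
    out = {}
    for model_id in dataset.model_ids:
        treated = dataset.curves_for(model_id, "treatment")
        vehicle = dataset.curves_for(model_id, "vehicle")
        if not treated or not vehicle:
            continue
        d = day
        if d is None:
            d = min(c.last_day for c in treated + vehicle)
        out[model_id] = tgi(treated, vehicle, d, variant="rtv")
    return out


def interpret_gene_effects(fit: LMMFit, gene_name: str = "Gene") -> dict:
    """Separate a gene's prognostic and predictive roles from a scan-style fit.

    ``Day:Gene`` (beta2) is the gene's effect on untreated growth (prognostic);
    ``Day:Gene:Treatment`` (beta4) is its modification of the treatment effect
    (predictive).  The report includes predicted mean growth-curve slopes at
    gene = -1, 0, +1 SD under both arms, and a plain-language narrative —
    opposite-signed effects of comparable magnitude are the pattern that lets
    a marker look beneficial or harmful depending on the trial population.
    """
    g_term = f"Day:{gene_name}"
    gx_term = f"Day:{gene_name}:Treatment"
    beta1 = fit.coef("Day")
    beta2 = fit.coef(g_term)
    beta3 = fit.coef("Day:Treatment") if "Day:Treatment" in fit.fixed_effects else 0.0
    beta4 = fit.coef(gx_term) if gx_term in fit.fixed_effects else 0.0

    def slope(g, treated):
        return beta1 + beta2 * g + (beta3 + beta4 * g) * (1 if treated else 0)

    curves = {
        (g, arm): slope(g, arm == "treatment")
        for g in (-1.0, 0.0, 1.0)
        for arm in ("vehicle", "treatment")
    }
    if beta2 == 0 and beta4 == 0:
        narrative = "No detectable prognostic or predictive effect."
    elif beta2 == 0:
        direction = "smaller" if beta4 > 0 else "larger"
        narrative = (
            "Purely predictive: expression does not change untreated growth, "
            f"but higher expression gives a {direction} treatment benefit."
        )
    elif beta4 == 0:
        direction = "slower" if beta2 < 0 else "faster"
        narrative = (
            f"Purely prognostic: higher expression means {direction} untreated "
            "growth; the treatment benefit is unchanged."
        )
    else:
        g_dir = "slower" if beta2 < 0 else "faster"
        t_dir = "smaller" if beta4 > 0 else "larger"
        narrative = (
            f"Higher expression: {g_dir} untreated growth, {t_dir} treatment "
            "benefit."
        )
        if beta2 * beta4 < 0:
            narrative += (
                " The two effects pull prognosis in opposite directions, so "
                "trials in different populations can reach conflicting "
                "conclusions about the marker."
            )
    return {
        "growth_effect": (beta2, fit.pvalue(g_term)),
        "treatment_modification": (
            beta4,
            fit.pvalue(gx_term) if gx_term in fit.fixed_effects else np.nan,
        ),
        "mean_growth_slopes": curves,
        "narrative": narrative,
    }
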
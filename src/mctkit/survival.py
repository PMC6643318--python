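"""Survival analysis for MCTs: endpoint derivation, Cox, and the additive
frailty model.

PFS and OS in a mouse study are tumor-volume doubling and tripling times.
Because mice are clustered within models (a model's mice share tumor
genetics), the usual independence assumption of the Cox model fails; the
additive frailty model puts two correlated normal random effects on each
cluster's log hazard,

    h_ij(t) = h0(t) * exp(u_i + (w + v_i) * T_ij + beta' X_i),

where u_i captures the model's intrinsic growth/hazard and v_i its
idiosyncratic drug response, (u_i, v_i) ~ N(0, [[sigma^2, rho*sigma*tau],
[rho*sigma*tau, tau^2]]).  Removing u and v recovers the Cox model — which,
fit naively to clustered data, attenuates the treatment hazard ratio toward
1.  The baseline is Weibull, h0(t) = (shape/scale) * (t/scale)^(shape-1),
and the marginal likelihood integrates the bivariate frailty per cluster by
adaptive Gauss-Hermite quadrature centered on the posterior mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import optimize, stats

from .datamodel import MCTDataset
from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    UndefinedEndpointError,
    ValidationError,
)
from .growth import time_to_multiple
from .continuous import _pooled_slope

_FACTORS = {"doubling": 2.0, "tripling": 3.0}


@dataclass(frozen=True)
class SurvivalRecord:
    """One mouse's event record. ``event`` is True when the volume threshold
    was crossed, False for censoring at the last measured day."""

    model_id: str
    mouse_id: str
    treatment: int
    time: float
    event: bool
    covariates: tuple = ()

    def __post_init__(self):
        if self.time <= 0:
            raise ValidationError(f"mouse {self.mouse_id}: time must be > 0")
        if self.treatment not in (0, 1):
            raise ValidationError("treatment must be 0 (vehicle) or 1 (drug)")


def derive_survival(dataset: MCTDataset, endpoint: str = "tripling") -> list:
    """Per-mouse doubling ("doubling", PFS) or tripling ("tripling", OS)
    times.  Mice with zero baseline volume are skipped with a warning; mice
    whose series never crosses are censored at their last measured day."""
    factor = _FACTORS[endpoint]
    records = []
    for curve in dataset.curves:
        try:
            res = time_to_multiple(curve, factor)
        except UndefinedEndpointError:
            warnings.warn(
                f"mouse {curve.mouse_id}: zero baseline, survival record skipped",
                stacklevel=2,
            )
            continue
        t = res["time"] if res["event"] else res["censored_at"]
        if t <= 0:  # crossing at initiation carries no survival information
            warnings.warn(
                f"mouse {curve.mouse_id}: non-positive event time skipped",
                stacklevel=2,
            )
            continue
        records.append(
            SurvivalRecord(
                model_id=curve.model_id,
                mouse_id=curve.mouse_id,
                treatment=1 if curve.arm == "treatment" else 0,
                time=float(t),
                event=bool(res["event"]),
            )
        )
    return records


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = [
        {
            "model_id": r.model_id,
            "mouse_id": r.mouse_id,
            "treatment": r.treatment,
            "time": r.time,
            "event": int(r.event),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def fit_cox(records: Sequence[SurvivalRecord]) -> dict:
    """Treatment-only Cox model (partial likelihood, Breslow ties) via
    lifelines; returns log HR, HR, and the 95% Wald CI."""
    df = records_to_frame(records)
    for arm in (0, 1):
        sub = df[df.treatment == arm]
        if sub.empty or sub.event.sum() == 0:
            raise InsufficientDataError(f"arm {arm}: no events; Cox fit undefined")
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[["time", "event", "treatment"]],
            duration_col="time",
            event_col="event",
        )
    except Exception as exc:  # lifelines raises on monotone likelihood
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    log_hr = float(cph.params_["treatment"])
    se = float(cph.standard_errors_["treatment"])
    return {
        "log_hr": log_hr,
        "se": se,
        "hazard_ratio": math.exp(log_hr),
        "ci_95": (math.exp(log_hr - 1.959964 * se), math.exp(log_hr + 1.959964 * se)),
    }


# --------------------------------------------------------------------------
# additive frailty model


@dataclass
class FrailtyFit:
    """Maximum-marginal-likelihood fit of the additive frailty model."""

    w: float
    se_w: float
    p_w: float
    beta: np.ndarray
    sigma2: float
    tau2: float
    rho: float
    se_log_sigma2: float
    se_log_tau2: float
    p_sigma2: float
    p_tau2: float
    weibull_shape: float
    weibull_scale: float
    hazard_ratio: float
    hazard_ratio_ci: tuple
    frailty_blups: Dict[str, tuple]
    log_marginal_likelihood: float
    converged: bool
    boundary: bool
    quadrature_points: int
    method: str  # "aghq" or "laplace"


class _FrailtyData:
    def __init__(self, records: Sequence[SurvivalRecord]):
        self.clusters = sorted({r.model_id for r in records})
        cindex = {c: i for i, c in enumerate(self.clusters)}
        self.nc = len(self.clusters)
        self.t = np.array([r.time for r in records])
        self.delta = np.array([float(r.event) for r in records])
        self.T = np.array([float(r.treatment) for r in records])
        self.ci = np.array([cindex[r.model_id] for r in records])
        k = len(records[0].covariates)
        self.X = np.array([r.covariates for r in records], dtype=float).reshape(
            len(records), k
        )
        self.logt = np.log(self.t)


def _cluster_stats(data: _FrailtyData, w, beta, shape, scale):
    """Per-cluster sufficient statistics of the conditional likelihood."""
    logH0 = shape * (data.logt - math.log(scale))
    logh0 = math.log(shape / scale) + (shape - 1.0) * (data.logt - math.log(scale))
    xb = data.X @ beta if beta.size else 0.0
    eta0 = w * data.T + xb
    r = np.exp(logH0 + eta0)
    nc = data.nc
    d0 = np.bincount(data.ci, weights=data.delta, minlength=nc)
    d1 = np.bincount(data.ci, weights=data.delta * data.T, minlength=nc)
    R0 = np.bincount(data.ci, weights=r * (1.0 - data.T), minlength=nc)
    R1 = np.bincount(data.ci, weights=r * data.T, minlength=nc)
    const = np.bincount(data.ci, weights=data.delta * (logh0 + eta0), minlength=nc)
    return d0, d1, R0, R1, const


def _posterior_modes(d0, d1, R0, R1, Sinv, n_iter=40):
    """Vectorized 2D Newton ascent of the per-cluster log-integrand."""
    nc = len(d0)
    u = np.zeros(nc)
    v = np.zeros(nc)
    for _ in range(n_iter):
        e0 = R0 * np.exp(u)
        e1 = R1 * np.exp(u + v)
        gu = d0 - e0 - e1 - (Sinv[0, 0] * u + Sinv[0, 1] * v)
        gv = d1 - e1 - (Sinv[1, 0] * u + Sinv[1, 1] * v)
        huu = e0 + e1 + Sinv[0, 0]
        huv = e1 + Sinv[0, 1]
        hvv = e1 + Sinv[1, 1]
        det = huu * hvv - huv * huv
        du = (hvv * gu - huv * gv) / det
        dv = (huu * gv - huv * gu) / det
        step = np.maximum(1.0, np.maximum(np.abs(du), np.abs(dv)) / 2.0)
        u = u + du / step
        v = v + dv / step
        if max(np.max(np.abs(gu)), np.max(np.abs(gv))) < 1e-10:
            break
    e0 = R0 * np.exp(u)
    e1 = R1 * np.exp(u + v)
    huu = e0 + e1 + Sinv[0, 0]
    huv = e1 + Sinv[0, 1]
    hvv = e1 + Sinv[1, 1]
    return u, v, huu, huv, hvv


def _marginal_loglik(
    data: _FrailtyData, w, beta, shape, scale, Sigma, gh_nodes, gh_logw, laplace=False
):
    d0, d1, R0, R1, const = _cluster_stats(data, w, beta, shape, scale)
    detS = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
    if detS <= 0:
        return -np.inf, None
    Sinv = np.array(
        [[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[0, 1], Sigma[0, 0]]]
    ) / detS
    u, v, huu, huv, hvv = _posterior_modes(d0, d1, R0, R1, Sinv)

    def log_joint(uu, vv):
        quad = (
            Sinv[0, 0] * uu**2 + 2.0 * Sinv[0, 1] * uu * vv + Sinv[1, 1] * vv**2
        )
        return (
            const[:, None]
            + d0[:, None] * uu
            + d1[:, None] * vv
            - R0[:, None] * np.exp(uu)
            - R1[:, None] * np.exp(uu + vv)
            - 0.5 * quad
            - 0.5 * math.log(detS)
            - math.log(2.0 * math.pi)
        )

    detH = huu * hvv - huv * huv
    if laplace:
        f0 = log_joint(u[:, None], v[:, None])[:, 0]
        ll = f0 + math.log(2.0 * math.pi) - 0.5 * np.log(detH)
        return float(np.sum(ll)), (u, v)

    # AGHQ: nodes x = mode + sqrt(2) * L z with L = chol(inv(H))
    # inv(H) = [[hvv, -huv], [-huv, huu]] / detH; lower Cholesky per cluster
    l11 = np.sqrt(hvv / detH)
    l21 = -huv / detH / l11
    l22 = np.sqrt(huu / detH - l21**2)
    za, zb = gh_nodes
    uu = u[:, None] + math.sqrt(2.0) * l11[:, None] * za[None, :]
    vv = v[:, None] + math.sqrt(2.0) * (
        l21[:, None] * za[None, :] + l22[:, None] * zb[None, :]
    )
    f = log_joint(uu, vv) + gh_logw[None, :] + za[None, :] ** 2 + zb[None, :] ** 2
    fmax = f.max(axis=1)
    ll = (
        fmax
        + np.log(np.sum(np.exp(f - fmax[:, None]), axis=1))
        + math.log(2.0)
        + np.log(l11 * l22)
    )
    return float(np.sum(ll)), (u, v)


def _gh_grid(n_quad):
    x, wts = np.polynomial.hermite.hermgauss(n_quad)
    za, zb = np.meshgrid(x, x, indexing="ij")
    logw = np.log(np.outer(wts, wts))
    return (za.ravel(), zb.ravel()), logw.ravel()


def fit_frailty(
    records: Sequence[SurvivalRecord],
    fix_rho: Optional[float] = None,
    fix_sigma2: Optional[float] = None,
    fix_tau2: Optional[float] = None,
    n_quad: int = 9,
    use_laplace: bool = False,
) -> FrailtyFit:
    """Fit the additive frailty model by maximum marginal likelihood.

    Variance parameters live on the log scale (Wald tests for sigma^2 > 0 and
    tau^2 > 0 are one-sided z tests of the delta-method ratio; an estimate at
    the lower boundary is flagged with p set to 1).  ``fix_*`` pins a
    parameter (e.g. ``fix_rho=0`` for small cluster counts, ``fix_tau2=0``
    to drop the response frailty).  Falls back to a Laplace approximation when
    ``use_laplace`` is set; otherwise adaptive Gauss-Hermite with
    ``n_quad``^2 points.
    """
    if not records:
        raise InsufficientDataError("no survival records")
    data = _FrailtyData(records)
    if data.nc < 5:
        raise InsufficientDataError("fit_frailty needs >= 5 clusters")
    if data.delta.sum() == 0:
        raise InsufficientDataError("no events")
    k = data.X.shape[1]
    gh_nodes, gh_logw = _gh_grid(n_quad)

    LOG_VAR_FLOOR = math.log(1e-6)

    # free-parameter bookkeeping: [w, beta..., log_shape, log_scale,
    # (log_s2), (log_t2), (atanh_rho)]
    free_names = ["w"] + [f"beta{i}" for i in range(k)] + ["log_shape", "log_scale"]
    if fix_sigma2 is None:
        free_names.append("log_s2")
    if fix_tau2 is None:
        free_names.append("log_t2")
    est_rho = fix_rho is None and fix_sigma2 != 0 and fix_tau2 != 0
    if est_rho:
        free_names.append("atanh_rho")

    ev_t = data.t[data.delta > 0]
    t_scale0 = float(np.median(ev_t)) if ev_t.size else float(np.median(data.t))

    def unpack(psi):
        i = 0
        w = psi[i]; i += 1
        beta = psi[i : i + k]; i += k
        shape = math.exp(psi[i]); i += 1
        scale = math.exp(psi[i]); i += 1
        if fix_sigma2 is None:
            s2 = math.exp(psi[i]); i += 1
        else:
            s2 = max(fix_sigma2, 1e-10)
        if fix_tau2 is None:
            t2 = math.exp(psi[i]); i += 1
        else:
            t2 = max(fix_tau2, 1e-10)
        rho = math.tanh(psi[i]) if est_rho else (fix_rho or 0.0)
        c = rho * math.sqrt(s2 * t2)
        Sigma = np.array([[s2, c], [c, t2]])
        return w, beta, shape, scale, Sigma

    def negll(psi):
        w, beta, shape, scale, Sigma = unpack(psi)
        ll, _ = _marginal_loglik(
            data, w, beta, shape, scale, Sigma, gh_nodes, gh_logw,
            laplace=use_laplace,
        )
        return -ll if np.isfinite(ll) else 1e12

    psi0 = np.zeros(len(free_names))
    psi0[free_names.index("log_shape")] = 0.0
    psi0[free_names.index("log_scale")] = math.log(t_scale0)
    if "log_s2" in free_names:
        psi0[free_names.index("log_s2")] = math.log(0.25)
    if "log_t2" in free_names:
        psi0[free_names.index("log_t2")] = math.log(0.1)

    bounds = []
    for name in free_names:
        if name in ("log_s2", "log_t2"):
            bounds.append((LOG_VAR_FLOOR, math.log(25.0)))
        elif name == "log_shape":
            bounds.append((math.log(0.05), math.log(20.0)))
        elif name == "log_scale":
            bounds.append((math.log(t_scale0) - 8.0, math.log(t_scale0) + 8.0))
        elif name == "atanh_rho":
            bounds.append((-4.0, 4.0))
        else:
            bounds.append((None, None))

    trace = []
    best = None
    for start_scale in (1.0, 0.5):
        psi = psi0 * start_scale
        psi[free_names.index("log_scale")] = math.log(t_scale0)
        res = optimize.minimize(
            negll, psi, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 400, "ftol": 1e-10},
        )
        trace.append((res.status, float(res.fun)))
        if best is None or res.fun < best.fun - 1e-8:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("frailty fit failed to converge", trace=trace)

    psi_hat = best.x
    w, beta, shape, scale, Sigma = unpack(psi_hat)
    ll, modes = _marginal_loglik(
        data, w, beta, shape, scale, Sigma, gh_nodes, gh_logw, laplace=use_laplace
    )

    # observed-information SEs by central-difference Hessian
    n_par = len(psi_hat)
    hess = np.zeros((n_par, n_par))
    h = 1e-4 * np.maximum(1.0, np.abs(psi_hat))
    f0 = negll(psi_hat)
    for a in range(n_par):
        for b in range(a, n_par):
            ea = np.zeros(n_par); ea[a] = h[a]
            eb = np.zeros(n_par); eb[b] = h[b]
            fpp = negll(psi_hat + ea + eb)
            fpm = negll(psi_hat + ea - eb)
            fmp = negll(psi_hat - ea + eb)
            fmm = negll(psi_hat - ea - eb)
            hess[a, b] = hess[b, a] = (fpp - fpm - fmp + fmm) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)

    se_of = dict(zip(free_names, se))
    se_w = float(se_of["w"])
    p_w = 2.0 * stats.norm.sf(abs(w) / se_w) if se_w > 0 else np.nan

    boundary = False
    def var_test(name, var_value, fixed):
        nonlocal boundary
        if fixed is not None:
            return np.nan, np.nan
        se_log = float(se_of[name])
        at_floor = math.log(var_value) <= LOG_VAR_FLOOR + 1e-6
        if at_floor:
            boundary = True
            return se_log, 1.0
        if not np.isfinite(se_log) or se_log == 0:
            return se_log, np.nan
        # one-sided z test of var/SE(var); SE(var) = var * SE(log var)
        z = 1.0 / se_log
        return se_log, float(stats.norm.sf(z))

    se_ls2, p_s2 = var_test("log_s2", Sigma[0, 0], fix_sigma2)
    se_lt2, p_t2 = var_test("log_t2", Sigma[1, 1], fix_tau2)
    if boundary:
        warnings.warn(
            "frailty variance estimate at lower boundary; its test p-value "
            "is reported as 1",
            stacklevel=2,
        )

    ci = (
        float(np.exp(w - 1.959964 * se_w)),
        float(np.exp(w + 1.959964 * se_w)),
    )  # np.exp: degenerate fits yield 0/inf rather than an overflow error
    rho_hat = Sigma[0, 1] / math.sqrt(Sigma[0, 0] * Sigma[1, 1])
    blups = {c: (float(modes[0][i]), float(modes[1][i])) for i, c in enumerate(data.clusters)}
    return FrailtyFit(
        w=float(w),
        se_w=se_w,
        p_w=float(p_w),
        beta=beta,
        sigma2=float(Sigma[0, 0]) if fix_sigma2 is None else float(fix_sigma2),
        tau2=float(Sigma[1, 1]) if fix_tau2 is None else float(fix_tau2),
        rho=float(rho_hat) if est_rho else (fix_rho or 0.0),
        se_log_sigma2=se_ls2,
        se_log_tau2=se_lt2,
        p_sigma2=p_s2,
        p_tau2=p_t2,
        weibull_shape=float(shape),
        weibull_scale=float(scale),
        hazard_ratio=math.exp(float(w)),
        hazard_ratio_ci=ci,
        frailty_blups=blups,
        log_marginal_likelihood=float(ll),
        converged=bool(best.success),
        boundary=boundary,
        quadrature_points=n_quad,
        method="laplace" if use_laplace else "aghq",
    )


def frailty_growth_correlation(
    fit: FrailtyFit, vehicle_growth_rates: Mapping[str, float]
) -> dict:
    """Correlation of the baseline frailty BLUPs u_i with per-model vehicle
    growth rates k_c.  Returns scatter data, Pearson r and R^2."""
    common = [c for c in fit.frailty_blups if c in vehicle_growth_rates]
    if len(common) < 3:
        raise InsufficientDataError("need >= 3 clusters with growth rates")
    u = np.array([fit.frailty_blups[c][0] for c in common])
    kc = np.array([vehicle_growth_rates[c] for c in common])
    if np.std(u) == 0 or np.std(kc) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(u, kc)[0, 1])
    return {
        "clusters": common,
        "u": u,
        "k_c": kc,
        "pearson_r": r,
        "r_squared": r**2,
    }


def vehicle_growth_rates(dataset: MCTDataset) -> Dict[str, float]:
    """Per-model pooled vehicle growth rate k_c (common slope, per-mouse
    intercepts), for use with :func:`frailty_growth_correlation`."""
    out = {}
    for model_id in dataset.model_ids:
        curves = dataset.curves_for(model_id, "vehicle")
        if curves:
            try:
                out[model_id] = _pooled_slope(curves)
            except InsufficientDataError:
                continue
    return out
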
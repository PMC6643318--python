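"""Restricted-maximum-likelihood engine for the three-level MCT mixed model.

Model, per observation t of mouse i in model (cluster) j:

    y_tij = x_tij' beta + z_t' u_j + z_t' u_{i|j} + eps_tij,   z_t = (1, day_t)

with u_j ~ N(0, G), u_{i|j} ~ N(0, H) (each an unstructured 2x2 covariance),
eps iid N(0, sigma^2), independence across levels.  sigma^2 is profiled out:
G and H are parameterized relative to sigma^2 through Cholesky factors, and
the REML criterion is minimized over those six parameters.

The per-cluster marginal covariance is factored with the Woodbury identity
around the block-diagonal mouse level, so each likelihood evaluation needs
only one small Cholesky per distinct measurement-day pattern plus 2x2
cluster algebra; evaluations are vectorized across mice.  This is what makes
the simulation-heavy procedures (type-I error, power grids, genome scans)
affordable in pure Python.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError

_LOG2PI = math.log(2.0 * math.pi)


def _chol_from_params(p3) -> np.ndarray:
    a, b, c = p3
    return np.array([[a, 0.0], [b, c]])


@dataclass
class REMLResult:
    beta: np.ndarray
    cov_beta: np.ndarray  # sampling covariance of beta
    sigma2: float
    G: np.ndarray  # model-level 2x2 covariance (absolute scale)
    H: np.ndarray  # mouse-level 2x2 covariance (absolute scale)
    loglik: float  # restricted log-likelihood
    theta: np.ndarray  # converged relative-scale parameters
    converged: bool
    n_obs: int
    n_iter: int


class _Prepared:
    """Observations regrouped by mouse and by measurement-day pattern."""

    def __init__(self, X, y, day, mouse_of_obs, model_of_mouse):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        day = np.asarray(day, float)
        mouse_of_obs = np.asarray(mouse_of_obs)
        self.n, self.p = X.shape
        self.n_models = int(np.max(model_of_mouse)) + 1
        self.n_mice = len(model_of_mouse)

        groups = {}
        for m in range(self.n_mice):
            idx = np.nonzero(mouse_of_obs == m)[0]
            order = idx[np.argsort(day[idx], kind="stable")]
            key = tuple(day[order])
            groups.setdefault(key, []).append((m, order))
        self.patterns = []
        for key, members in groups.items():
            d = np.asarray(key)
            Z = np.column_stack([np.ones_like(d), d])
            Xs = np.stack([X[order] for _, order in members])
            ys = np.stack([y[order] for _, order in members])
            models = np.array([model_of_mouse[m] for m, _ in members])
            self.patterns.append({"Z": Z, "X": Xs, "y": ys, "model": models})


def _neg2_reml(theta, prep: _Prepared, want_fit: bool = False):
    Lg = _chol_from_params(theta[:3])
    Lh = _chol_from_params(theta[3:])
    G = Lg @ Lg.T
    H = Lh @ Lh.T

    p = prep.p
    nm = prep.n_models
    logdet_D = 0.0
    # per-model accumulators
    M = np.zeros((nm, 2, 2))
    Cx = np.zeros((nm, 2, p))
    Cy = np.zeros((nm, 2))
    S_xx = np.zeros((p, p))
    S_xy = np.zeros(p)
    S_yy = 0.0

    for pat in prep.patterns:
        Z = pat["Z"]
        nt = Z.shape[0]
        A = Z @ H @ Z.T + np.eye(nt)
        sign, ld = np.linalg.slogdet(A)
        if sign <= 0:
            return (np.inf, None) if want_fit else np.inf
        Ainv = np.linalg.inv(A)
        Xs, ys, models = pat["X"], pat["y"], pat["model"]
        m = Xs.shape[0]
        logdet_D += m * ld
        AiX = np.einsum("nk,mkj->mnj", Ainv, Xs, optimize=True)
        Aiy = ys @ Ainv
        S_xx += np.einsum("mni,mnj->ij", Xs, AiX, optimize=True)
        S_xy += np.einsum("mni,mn->i", AiX, ys, optimize=True)
        S_yy += float(np.einsum("mn,mn->", ys, Aiy))
        ZtAi = Z.T @ Ainv  # (2, nt)
        ZtAiZ = ZtAi @ Z  # (2, 2), same for every mouse in the pattern
        ZtAiX = np.einsum("kn,mnj->mkj", ZtAi, Xs, optimize=True)
        ZtAiy = ys @ ZtAi.T
        # segment-sum per model (bincount beats np.add.at by a wide margin)
        counts = np.bincount(models, minlength=nm)
        M += counts[:, None, None] * ZtAiZ
        for a in range(2):
            Cy[:, a] += np.bincount(models, weights=ZtAiy[:, a], minlength=nm)
            for b in range(p):
                Cx[:, a, b] += np.bincount(
                    models, weights=ZtAiX[:, a, b], minlength=nm
                )

    # batched 2x2 cluster algebra
    K = np.eye(2)[None] + M @ G  # (nm, 2, 2)
    detK = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
    if np.any(detK <= 0):
        return (np.inf, None) if want_fit else np.inf
    Kinv = (
        np.stack(
            [K[:, 1, 1], -K[:, 0, 1], -K[:, 1, 0], K[:, 0, 0]], axis=-1
        ).reshape(nm, 2, 2)
        / detK[:, None, None]
    )
    P = G[None] @ Kinv  # == (G^-1 + M_j)^-1, valid for singular G
    P = 0.5 * (P + np.swapaxes(P, 1, 2))
    PCx = P @ Cx  # (nm, 2, p)
    PCy = np.einsum("jab,jb->ja", P, Cy)
    XtWX = S_xx - np.einsum("jap,jaq->pq", Cx, PCx)
    XtWy = S_xy - np.einsum("jap,ja->p", Cx, PCy)
    ytWy = S_yy - float(np.einsum("ja,ja->", Cy, PCy))
    logdet_W = logdet_D + float(np.sum(np.log(detK)))

    try:
        cF = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return (np.inf, None) if want_fit else np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    dfe = prep.n - prep.p
    if rss <= 0 or dfe <= 0:
        return (np.inf, None) if want_fit else np.inf
    sigma2 = rss / dfe
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(cF))))
    crit = logdet_W + dfe * math.log(sigma2) + logdet_XtWX
    if not want_fit:
        return crit
    loglik = -0.5 * (crit + dfe * (1.0 + _LOG2PI))
    cov_beta = np.linalg.inv(XtWX) * sigma2
    return crit, {
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma2": sigma2,
        "G": G * sigma2,
        "H": H * sigma2,
        "loglik": loglik,
    }


_DEFAULT_STARTS = (
    np.array([1.0, 0.0, 0.1, 1.0, 0.0, 0.1]),
    np.array([0.3, 0.0, 0.03, 0.3, 0.0, 0.03]),
    np.array([2.0, 0.0, 0.3, 0.5, 0.0, 0.05]),
)


def fit_reml(
    X,
    y,
    day,
    mouse_of_obs,
    model_of_mouse,
    theta0: Optional[np.ndarray] = None,
    maxiter: int = 300,
) -> REMLResult:
    """Fit the three-level model by REML.

    ``mouse_of_obs`` maps each observation to a mouse index; ``model_of_mouse``
    maps each mouse index to its model (cluster) index.  ``theta0`` warm-starts
    the relative-scale Cholesky parameters (useful in genome scans).  Restarts
    from deterministic points on failure; raises ConvergenceError if all fail.
    """
    prep = _Prepared(X, y, day, mouse_of_obs, model_of_mouse)
    starts = list(_DEFAULT_STARTS)
    if theta0 is not None:
        starts.insert(0, np.asarray(theta0, float))
    trace = []
    best = None
    for s in starts:
        res = optimize.minimize(
            _neg2_reml,
            s,
            args=(prep,),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6},
        )
        trace.append((list(s), res.status, float(res.fun)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-8):
            best = res
        if best is not None and res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed from all starts", trace=trace)
    crit, fit = _neg2_reml(best.x, prep, want_fit=True)
    if fit is None:
        raise ConvergenceError("REML criterion non-finite at optimum", trace=trace)
    return REMLResult(
        beta=fit["beta"],
        cov_beta=fit["cov_beta"],
        sigma2=fit["sigma2"],
        G=fit["G"],
        H=fit["H"],
        loglik=fit["loglik"],
        theta=np.asarray(best.x),
        converged=bool(best.success),
        n_obs=prep.n,
        n_iter=int(best.nit),
    )
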
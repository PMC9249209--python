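"""Mixed-model estimation machinery.

Two estimators, both with a site (cluster) random intercept and optionally a
second random coefficient:

* :func:`fit_lmm` — Gaussian linear mixed model for log length-of-stay.  The
  likelihood is evaluated cluster-by-cluster with the Woodbury identity, the
  fixed effects and residual variance are profiled out by generalised least
  squares, and the remaining variance-ratio parameters are optimised
  numerically (REML by default).  A random intercept per site is exactly the
  compound-symmetry within-site covariance.  Per-row frequency weights are
  supported, which plain off-the-shelf mixed-model routines in the scientific
  Python stack do not offer — this is what inverse-probability weighting
  needs.

* :func:`fit_logistic_glmm` — logistic mixed model for the rare binary
  safety event, maximising the marginal likelihood in which each cluster's
  random effect is integrated out.  The integral is approximated by adaptive
  Gauss–Hermite quadrature with the nodes centred and scaled at the
  conditional mode (``n_nodes = 1`` is the Laplace approximation).  The
  random effects are parameterised through the scaled (Cholesky) form
  ``u = Lambda v`` so that the zero-variance boundary is an interior-smooth
  point of the objective and degenerates exactly to plain logistic
  regression.

Both report the exponentiated intervention coefficient (odds ratio or
geometric mean ratio) with a Wald 95% confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import integrate, optimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "DesignMatrices", "FitResult", "natural_cubic_spline_basis", "wald_ci",
    "fit_lmm", "fit_logistic_glmm", "cluster_marglik_oracle",
]

_MAX_ITER = 500
_GTOL = 1e-8


# ----------------------------------------------------------------------
# Spline basis
# ----------------------------------------------------------------------

def natural_cubic_spline_basis(x, n_knots: int, knots=None, boundary=None):
    """Natural cubic spline basis (no intercept column).

    Interior knots sit at equally spaced quantiles of ``x``; boundary knots
    at min/max.  With ``m = n_knots`` interior knots the basis has ``m + 1``
    columns (the classic truncated-power natural-spline construction), is
    linear beyond the boundary knots, and reproduces any linear function of
    ``x`` exactly within its span.
    """
    x = np.asarray(x, dtype=float)
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("cannot build a spline basis on a constant covariate")
    if boundary is None:
        boundary = (x.min(), x.max())
    if knots is None:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        knots = np.quantile(x, qs)
    knots = np.unique(np.asarray(knots, dtype=float))
    all_knots = np.unique(np.concatenate([[boundary[0]], knots, [boundary[1]]]))
    K = len(all_knots)
    if K < 3:
        raise ValueError("need at least 3 distinct knots (interior + boundary)")

    def d(j):  # divided truncated cubic differences
        num = np.maximum(x - all_knots[j], 0.0) ** 3 - np.maximum(x - all_knots[K - 1], 0.0) ** 3
        return num / (all_knots[K - 1] - all_knots[j])

    cols = [x]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    return np.column_stack(cols)


# ----------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Assembled fixed-effect matrix plus outcome, clusters and weights."""

    X: np.ndarray
    columns: list
    y: np.ndarray
    cluster_index: np.ndarray            # integer codes 0..C-1
    cluster_labels: list
    Z_spec: str = "intercept"            # intercept | intercept+<column name>
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.X.shape[0]
        if not (len(self.y) == n == len(self.cluster_index)):
            raise ValueError("X, y and cluster_index must have equal length")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match the design matrix width")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            raise ValueError(
                f"fixed-effects matrix is rank deficient (rank {rank} < "
                f"{self.X.shape[1]}); columns: {self.columns}"
            )

    @property
    def n_clusters(self):
        return int(self.cluster_index.max()) + 1 if len(self.cluster_index) else 0

    def random_effect_design(self):
        """Per-row random-effect design Z (n x q)."""
        n = self.X.shape[0]
        if self.Z_spec == "intercept":
            return np.ones((n, 1))
        if self.Z_spec.startswith("intercept+"):
            name = self.Z_spec.split("+", 1)[1]
            if name not in self.columns:
                raise ValueError(f"random-slope column {name!r} not in the design")
            return np.column_stack([np.ones(n), self.X[:, self.columns.index(name)]])
        raise ValueError(f"unknown Z_spec {self.Z_spec!r}")


@dataclass
class FitResult:
    """Coefficients, covariance, variance components and the headline effect."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    random_effect_sd: dict
    loglik: float
    converged: bool
    n_used: int
    method: str
    effect: dict = field(default_factory=dict)
    boundary: bool = False
    label: str = ""

    @property
    def se(self):
        return pd.Series(np.sqrt(np.diag(self.cov_beta.to_numpy())), index=self.beta.index)

    def term_ci(self, term, level=0.95):
        return wald_ci(self.beta[term], self.se[term], level)

    def summary_frame(self):
        se = self.se
        lo, hi = wald_ci(self.beta.to_numpy(), se.to_numpy())
        return pd.DataFrame(
            {"term": self.beta.index, "estimate": self.beta.to_numpy(),
             "se": se.to_numpy(), "ci_low": lo, "ci_high": hi}
        )

    def to_csv(self, path, metadata=None):
        self.summary_frame().to_csv(path, index=False)
        meta = {
            "method": self.method, "converged": bool(self.converged),
            "boundary": bool(self.boundary), "n_used": int(self.n_used),
            "loglik": float(self.loglik),
            "random_effect_sd": {k: float(v) for k, v in self.random_effect_sd.items()},
            "effect": self.effect, "label": self.label,
        }
        if metadata:
            meta.update(metadata)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def wald_ci(coef, se, level=0.95):
    """Wald confidence interval ``coef +/- z * se`` (log scale upstream of
    any exponentiation for OR/GMR reporting)."""
    z = norm.ppf(0.5 + level / 2.0)
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    lo, hi = coef - z * se, coef + z * se
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def _attach_effect(fit: FitResult, scale: str, term="intervention", level=0.95):
    if term in fit.beta.index:
        lo, hi = fit.term_ci(term, level)
        fit.effect = {
            "scale": scale, "term": term,
            "estimate": float(np.exp(fit.beta[term])),
            "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
            "log_estimate": float(fit.beta[term]), "log_se": float(fit.se[term]),
        }
    return fit


# ----------------------------------------------------------------------
# Linear mixed model (profiled GLS, REML default, frequency weights)
# ----------------------------------------------------------------------

def _lmm_profile(theta, X, y, w, Z, ci, n_clusters, reml):
    """Profiled -2 log-likelihood for the scaled covariance parameters.

    ``theta`` parameterises Lambda, the lower Cholesky factor of
    Sigma_b / sigma_e^2 (log-diagonal).  beta and sigma_e^2 are profiled.
    """
    q = Z.shape[1]
    Lam = _theta_to_chol(theta, q)
    G = Lam @ Lam.T
    p = X.shape[1]
    n = len(y)
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = -np.sum(np.log(w))
    for c in range(n_clusters):
        idx = np.flatnonzero(ci == c)
        Xc, yc, wc, Zc = X[idx], y[idx], w[idx], Z[idx]
        M = Zc.T @ (wc[:, None] * Zc)                      # Z'WZ
        A = np.eye(q) + G @ M
        logdet += float(np.log(np.linalg.det(A)))
        # V*^-1 x = W x - W Z G (I + M G)^-1 Z' W x
        B = np.linalg.solve(np.eye(q) + M @ G, Zc.T)       # (I+MG)^-1 Z'
        WX, Wy = wc[:, None] * Xc, wc * yc
        ZtWX, ZtWy = Zc.T @ WX, Zc.T @ Wy
        corrX = (wc[:, None] * (Zc @ G)) @ (B @ WX)        # WZG(I+MG)^-1 Z'WX
        ViX = WX - corrX
        XtViX += Xc.T @ ViX
        XtViy += ViX.T @ yc
        ytViy += float(Wy @ yc - (Wy @ (Zc @ G)) @ (B @ Wy))
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - float(beta @ XtViy)
    dof = n - p if reml else n
    sigma2 = max(rss / dof, 1e-300)
    crit = dof * np.log(sigma2) + logdet
    if reml:
        sign, ld = np.linalg.slogdet(XtViX)
        crit += ld
    return crit, beta, sigma2, XtViX


def _theta_to_chol(theta, q):
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


def fit_lmm(dm: DesignMatrices, reml: bool = True) -> FitResult:
    """Random-intercept(/slope) Gaussian mixed model with frequency weights.

    REML by default.  The random intercept per site reproduces the
    compound-symmetry within-site marginal covariance.  The geometric mean
    ratio is ``exp`` of the intervention coefficient with a Wald 95% CI.
    """
    X, y, w = dm.X, dm.y, dm.weights
    Z = dm.random_effect_design()
    q = Z.shape[1]
    ci = dm.cluster_index
    nC = dm.n_clusters
    n_theta = q * (q + 1) // 2
    theta0 = np.zeros(n_theta)
    diag_pos = np.cumsum(np.arange(1, q + 1)) - 1
    theta0[diag_pos] = np.log(0.3)
    bounds = [(-30.0, 10.0) if k in diag_pos else (-50.0, 50.0) for k in range(n_theta)]

    def obj(theta):
        return _lmm_profile(theta, X, y, w, Z, ci, nC, reml)[0]

    res = optimize.minimize(
        obj, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAX_ITER, "ftol": 1e-12, "gtol": _GTOL},
    )
    if not res.success:
        # the profile surface is flat near a zero-variance boundary and can
        # defeat the line search; a simplex restart settles it
        alt = optimize.minimize(
            obj, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if alt.fun <= res.fun + 1e-9:
            res = alt
    crit, beta, sigma2, XtViX = _lmm_profile(res.x, X, y, w, Z, ci, nC, reml)
    Lam = _theta_to_chol(res.x, q)
    G = Lam @ Lam.T
    ratio = np.sqrt(np.maximum(np.diag(G), 0.0))   # re sd / residual sd
    re_sd = ratio * np.sqrt(sigma2)
    boundary = bool(np.any(ratio < 1e-3))
    re_sd = np.where(ratio < 1e-4, 0.0, re_sd)
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    n = len(y)
    const = (n - X.shape[1] if reml else n) * (1 + np.log(2 * np.pi))
    loglik = -0.5 * (crit + const)
    re_names = ["intercept"] if q == 1 else ["intercept", dm.Z_spec.split("+", 1)[1]]
    fit = FitResult(
        beta=pd.Series(beta, index=dm.columns),
        cov_beta=pd.DataFrame(cov_beta, index=dm.columns, columns=dm.columns),
        random_effect_sd={**dict(zip(re_names, re_sd)), "residual": float(np.sqrt(sigma2))},
        loglik=float(loglik),
        converged=bool(res.success),
        n_used=n,
        method="LMM-REML" if reml else "LMM-ML",
        boundary=boundary,
    )
    return _attach_effect(fit, "GMR")


# ----------------------------------------------------------------------
# Logistic GLMM: adaptive Gauss-Hermite / Laplace marginal likelihood
# ----------------------------------------------------------------------

def _bern_loglik(eta, y, w):
    # w * (y*eta - log(1+exp(eta))), numerically stable
    return w * (y * eta - np.logaddexp(0.0, eta))


def _find_modes_q1(eta, y, w, ci, nC, sigma, v0=None, tol=1e-10, max_iter=50):
    """Conditional modes v-hat of the scaled random effect (u = sigma*v),
    one scalar Newton iteration per cluster, vectorised across clusters."""
    v = np.zeros(nC) if v0 is None else v0.copy()
    if sigma == 0.0:
        return v
    for _ in range(max_iter):
        p = expit(eta + sigma * v[ci])
        grad = sigma * np.bincount(ci, weights=w * (y - p), minlength=nC) - v
        hess = (sigma ** 2) * np.bincount(ci, weights=w * p * (1 - p), minlength=nC) + 1.0
        step = grad / hess
        v += step
        if np.max(np.abs(grad)) < tol:
            break
    return v


def _laplace_q1(params, X, y, w, ci, nC, eta_cache=None, v0=None, want_grad=False):
    """Laplace log marginal likelihood (and gradient) for the scalar
    random-intercept model; parameters are (beta, sigma)."""
    p_dim = X.shape[1]
    beta, sigma = params[:p_dim], max(params[p_dim], 0.0)
    eta0 = X @ beta
    v = _find_modes_q1(eta0, y, w, ci, nC, sigma, v0=v0)
    eta = eta0 + sigma * v[ci]
    prob = expit(eta)
    pw = w * prob * (1 - prob)
    Sw = np.bincount(ci, weights=pw, minlength=nC)
    denom = 1.0 + sigma ** 2 * Sw                         # = sigma^2 * H
    ll = float(np.sum(_bern_loglik(eta, y, w)) - 0.5 * np.sum(v ** 2)
               - 0.5 * np.sum(np.log(denom)))
    if not want_grad:
        return ll, v
    H = Sw + (1.0 / sigma ** 2 if sigma > 0 else np.inf)
    resid = w * (y - prob)
    t0_row = pw * (1 - 2 * prob)
    T0 = np.bincount(ci, weights=t0_row, minlength=nC)
    grad = np.empty(p_dim + 1)
    if sigma == 0.0:
        grad[:p_dim] = X.T @ resid
        grad[p_dim] = 0.0
        return ll, v, grad
    Sk = np.zeros((nC, p_dim))
    Tk = np.zeros((nC, p_dim))
    np.add.at(Sk, ci, pw[:, None] * X)
    np.add.at(Tk, ci, t0_row[:, None] * X)
    grad[:p_dim] = X.T @ resid - 0.5 * np.sum(Tk / H[:, None], axis=0) \
        + 0.5 * np.sum((T0 / H ** 2)[:, None] * Sk, axis=0)
    u = sigma * v
    grad[p_dim] = float(np.sum(u ** 2 / sigma ** 3 - Sw / (sigma * H)
                               - u * T0 / (sigma ** 3 * H ** 2)))
    return ll, v, grad


def _agq_q1(params, X, y, w, ci, nC, n_nodes, v0=None):
    """Adaptive Gauss-Hermite log marginal likelihood, scalar random effect."""
    p_dim = X.shape[1]
    beta, sigma = params[:p_dim], max(params[p_dim], 0.0)
    eta0 = X @ beta
    if sigma == 0.0:
        return float(np.sum(_bern_loglik(eta0, y, w))), np.zeros(nC)
    v = _find_modes_q1(eta0, y, w, ci, nC, sigma, v0=v0)
    eta = eta0 + sigma * v[ci]
    prob = expit(eta)
    Sw = np.bincount(ci, weights=w * prob * (1 - prob), minlength=nC)
    s2H = 1.0 + sigma ** 2 * Sw                           # sigma^2 * H
    s = sigma / np.sqrt(s2H)                              # adaptive scale 1/sqrt(H)
    z, om = hermgauss(n_nodes)
    logw = np.log(om)
    # v-scale node positions per cluster: v_m = v-hat + sqrt(2) * (s/sigma) * z_m
    contrib = np.empty((nC, n_nodes))
    for m in range(n_nodes):
        vm = v + np.sqrt(2.0) * (s / sigma) * z[m]
        etam = eta0 + sigma * vm[ci]
        bern = np.bincount(ci, weights=_bern_loglik(etam, y, w), minlength=nC)
        contrib[:, m] = logw[m] + z[m] ** 2 + bern - 0.5 * vm ** 2
    mx = contrib.max(axis=1)
    lse = mx + np.log(np.sum(np.exp(contrib - mx[:, None]), axis=1))
    ll = float(np.sum(lse + np.log(s / sigma) - 0.5 * np.log(np.pi)))
    return ll, v


def _logistic_irls(X, y, w, max_iter=25, tol=1e-10):
    """Plain weighted logistic regression (starting values)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.average(y, weights=w), 1e-8) /
                     max(1 - np.average(y, weights=w), 1e-8)) if np.any(y) else -8.0
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        pw = np.clip(w * p * (1 - p), 1e-12, None)
        grad = X.T @ (w * (y - p))
        H = X.T @ (pw[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta += step
        if np.max(np.abs(grad)) < tol:
            break
    return beta


def _glmm_cov_beta(X, y, w, ci, nC, beta, sigma, v):
    """Fixed-effect covariance from the profiled penalised information:
    X'WX minus the Schur complement for the conditional modes."""
    eta = X @ beta + sigma * v[ci]
    prob = expit(eta)
    pw = w * prob * (1 - prob)
    info = X.T @ (pw[:, None] * X)
    if sigma > 0:
        Sw = np.bincount(ci, weights=pw, minlength=nC)
        H = Sw + 1.0 / sigma ** 2
        Sk = np.zeros((nC, X.shape[1]))
        np.add.at(Sk, ci, pw[:, None] * X)
        info = info - (Sk / H[:, None]).T @ Sk
    return np.linalg.inv(info)


def _fit_glmm_q1(dm: DesignMatrices, method: str, n_nodes: int) -> FitResult:
    X, y, w, ci = dm.X, dm.y, dm.weights, np.asarray(dm.cluster_index)
    nC = dm.n_clusters
    p_dim = X.shape[1]
    beta0 = _logistic_irls(X, y, w)
    x0 = np.append(beta0, 0.1)
    bounds = [(None, None)] * p_dim + [(0.0, 10.0)]
    state = {"v": None}

    if method == "laplace":
        def fun_jac(params):
            ll, v, g = _laplace_q1(params, X, y, w, ci, nC, v0=state["v"], want_grad=True)
            state["v"] = v
            return -ll, -g
        res = optimize.minimize(
            fun_jac, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": _MAX_ITER, "gtol": _GTOL, "ftol": 1e-13},
        )
    else:  # adaptive Gauss-Hermite: warm start from Laplace, numeric gradient
        def fj(params):
            ll, v, g = _laplace_q1(params, X, y, w, ci, nC, v0=state["v"], want_grad=True)
            state["v"] = v
            return -ll, -g
        warm = optimize.minimize(
            fj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": _MAX_ITER, "gtol": _GTOL, "ftol": 1e-13},
        )

        def fun(params):
            ll, v = _agq_q1(params, X, y, w, ci, nC, n_nodes, v0=state["v"])
            state["v"] = v
            return -ll
        res = optimize.minimize(
            fun, warm.x, jac="2-point", method="L-BFGS-B", bounds=bounds,
            options={"maxiter": _MAX_ITER, "gtol": 1e-6, "ftol": 1e-12},
        )

    converged = bool(res.success)
    if not converged:
        # restart from a larger random-effect SD
        for s0 in (0.1, 1.0):
            x_r = np.append(beta0, s0)
            if method == "laplace":
                res2 = optimize.minimize(
                    fun_jac, x_r, jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": _MAX_ITER, "gtol": _GTOL},
                )
            else:
                res2 = optimize.minimize(
                    fun, x_r, jac="2-point", method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": _MAX_ITER, "gtol": 1e-6},
                )
            if res2.success and res2.fun <= res.fun + 1e-8:
                res, converged = res2, True
                break

    beta = res.x[:p_dim]
    sigma = max(res.x[p_dim], 0.0)
    boundary = sigma < 1e-3
    if sigma < 1e-4:
        sigma = 0.0
    if method == "laplace":
        ll, v = _laplace_q1(np.append(beta, sigma), X, y, w, ci, nC)[:2]
    else:
        ll, v = _agq_q1(np.append(beta, sigma), X, y, w, ci, nC, n_nodes)
    cov = _glmm_cov_beta(X, y, w, ci, nC, beta, sigma, v)
    fit = FitResult(
        beta=pd.Series(beta, index=dm.columns),
        cov_beta=pd.DataFrame(cov, index=dm.columns, columns=dm.columns),
        random_effect_sd={"intercept": float(sigma)},
        loglik=float(ll),
        converged=converged,
        n_used=len(y),
        method="Laplace" if method == "laplace" else f"AGQ({n_nodes})",
        boundary=boundary,
    )
    return _attach_effect(fit, "OR")


# -- two-dimensional random effects (Laplace only) ---------------------

def _modes_q2(eta0, y, w, Zs, ci, nC, tol=1e-9, max_iter=60):
    """Per-cluster Newton for the scaled 2-d random effect v (u = Lambda v);
    Zs = Z @ Lambda."""
    V = np.zeros((nC, 2))
    for c in range(nC):
        idx = np.flatnonzero(ci == c)
        Zc, yc, wc, ec = Zs[idx], y[idx], w[idx], eta0[idx]
        v = V[c]
        for _ in range(max_iter):
            p = expit(ec + Zc @ v)
            g = Zc.T @ (wc * (yc - p)) - v
            Hm = Zc.T @ ((wc * p * (1 - p))[:, None] * Zc) + np.eye(2)
            step = np.linalg.solve(Hm, g)
            v = v + step
            if np.max(np.abs(g)) < tol:
                break
        V[c] = v
    return V


def _laplace_q2(params, X, y, w, Z, ci, nC):
    p_dim = X.shape[1]
    beta = params[:p_dim]
    Lam = _theta_to_chol(params[p_dim:], 2)
    Zs = Z @ Lam                 # u = Lam v  =>  eta contribution is (Z Lam) v
    eta0 = X @ beta
    V = _modes_q2(eta0, y, w, Zs, ci, nC)
    eta = eta0 + np.einsum("ij,ij->i", Zs, V[ci])
    prob = expit(eta)
    pw = w * prob * (1 - prob)
    ll = float(np.sum(_bern_loglik(eta, y, w))) - 0.5 * float(np.sum(V ** 2))
    for c in range(nC):
        idx = np.flatnonzero(ci == c)
        Zc = Zs[idx]
        Hm = Zc.T @ (pw[idx][:, None] * Zc) + np.eye(2)
        ll -= 0.5 * float(np.log(np.linalg.det(Hm)))
    return ll, V, Zs


def _fit_glmm_q2(dm: DesignMatrices) -> FitResult:
    X, y, w, ci = dm.X, dm.y, dm.weights, np.asarray(dm.cluster_index)
    Z = dm.random_effect_design()
    nC = dm.n_clusters
    p_dim = X.shape[1]
    beta0 = _logistic_irls(X, y, w)
    theta0 = np.array([np.log(0.1), 0.0, np.log(0.1)])
    x0 = np.concatenate([beta0, theta0])
    bounds = [(None, None)] * p_dim + [(-12.0, 3.0), (-5.0, 5.0), (-12.0, 3.0)]

    def fun(params):
        return -_laplace_q2(params, X, y, w, Z, ci, nC)[0]

    res = optimize.minimize(
        fun, x0, jac="2-point", method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAX_ITER, "gtol": 1e-6, "ftol": 1e-12},
    )
    beta = res.x[:p_dim]
    Lam = _theta_to_chol(res.x[p_dim:], 2)
    Sig = Lam @ Lam.T
    re_sd = np.sqrt(np.maximum(np.diag(Sig), 0.0))
    boundary = bool(np.any(res.x[[p_dim, p_dim + 2]] <= -11.0))
    ll, V, Zs = _laplace_q2(res.x, X, y, w, Z, ci, nC)
    # covariance conditional on the modes (Schur complement per cluster)
    eta = X @ beta + np.einsum("ij,ij->i", Zs, V[ci])
    prob = expit(eta)
    pw = w * prob * (1 - prob)
    info = X.T @ (pw[:, None] * X)
    for c in range(nC):
        idx = np.flatnonzero(ci == c)
        Zc, Xc = Zs[idx], X[idx]
        S = Zc.T @ (pw[idx][:, None] * Xc)
        Hm = Zc.T @ (pw[idx][:, None] * Zc) + np.eye(2)
        info -= S.T @ np.linalg.solve(Hm, S)
    cov = np.linalg.inv(info)
    slope_name = dm.Z_spec.split("+", 1)[1]
    fit = FitResult(
        beta=pd.Series(beta, index=dm.columns),
        cov_beta=pd.DataFrame(cov, index=dm.columns, columns=dm.columns),
        random_effect_sd={"intercept": float(re_sd[0]), slope_name: float(re_sd[1])},
        loglik=float(ll),
        converged=bool(res.success),
        n_used=len(y),
        method="Laplace",
        boundary=boundary,
    )
    return _attach_effect(fit, "OR")


def fit_logistic_glmm(dm: DesignMatrices, method: str = "laplace", n_nodes: int = 25) -> FitResult:
    """Random-intercept(/slope) logistic mixed model.

    ``method='agq'`` uses adaptive Gauss-Hermite quadrature with ``n_nodes``
    (scalar random effect only); ``method='laplace'`` is the one-node case
    and is the only estimator offered for two-dimensional random effects.
    Per-row weights multiply log-likelihood contributions (frequency-style).
    A variance estimate at the zero boundary is reported as 0 with the
    ``boundary`` flag set rather than raised as an error.
    """
    if not set(np.unique(dm.y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    method = method.lower()
    if method not in {"laplace", "agq"}:
        raise ValueError(f"method must be 'laplace' or 'agq', got {method!r}")
    q = dm.random_effect_design().shape[1]
    if q == 1:
        return _fit_glmm_q1(dm, method, n_nodes)
    if method == "agq":
        raise ValueError("adaptive quadrature is only available for a scalar "
                         "random intercept; use method='laplace' for random slopes")
    return _fit_glmm_q2(dm)


# ----------------------------------------------------------------------
# Brute-force integration oracle
# ----------------------------------------------------------------------

def cluster_marglik_oracle(X, y, beta, sigma_u, weights=None):
    """Log marginal likelihood of one cluster by brute-force adaptive
    numerical integration (absolute tolerance ~1e-10 on the integral).

    Independent of the quadrature code path: integrates the product of
    Bernoulli likelihoods against the Gaussian random-intercept density
    directly with ``scipy.integrate.quad``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if len(y) > 100:
        raise ValueError("oracle is intended for small clusters (<=100 rows)")
    eta0 = X @ np.asarray(beta, dtype=float)
    if sigma_u == 0.0:
        return float(np.sum(_bern_loglik(eta0, y, w)))

    def log_integrand(u):
        return (np.sum(_bern_loglik(eta0 + u, y, w))
                - 0.5 * u ** 2 / sigma_u ** 2
                - 0.5 * np.log(2 * np.pi * sigma_u ** 2))

    # centre the integration at the (1-d) mode for numerical headroom
    from scipy.optimize import minimize_scalar
    m = minimize_scalar(lambda u: -log_integrand(u),
                        bounds=(-20 * sigma_u, 20 * sigma_u), method="bounded")
    shift = -m.fun
    lo, hi = m.x - 15 * sigma_u, m.x + 15 * sigma_u
    val, _ = integrate.quad(lambda u: np.exp(log_integrand(u) - shift),
                            lo, hi, epsabs=1e-12, epsrel=1e-12, limit=200)
    return float(shift + np.log(val))
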
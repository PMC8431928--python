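"""Fixed- and random-intercept regression models for provider profiling.

Families
--------
``binary_logit``
    P(y=1) = expit(x'b), fitted by iteratively reweighted least squares.
``ordinal_logit``
    Proportional odds with the convention logit P(Y <= k) = theta_k - x'b,
    so a positive coefficient means higher odds of a *worse* category.
``gaussian``
    Ordinary linear model.

Random-intercept extensions integrate a Normal(0, tau^2) centre effect out
of the likelihood by adaptive Gauss-Hermite quadrature (one node is the
Laplace approximation); the gaussian case uses closed-form marginal
likelihood with the fixed effects profiled out by GLS. Empirical-Bayes
posterior means and SDs of the centre intercepts are returned alongside
the fit, together with the sampling SE of each centre's unshrunken
deviation (the quantity rankability needs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

_SQRT2 = np.sqrt(2.0)
_LOG_TAU_MIN, _LOG_TAU_MAX = np.log(1e-6), np.log(50.0)
_TAU_BOUNDARY = 1e-3  # below this the SD is reported as a boundary zero


class InputError(ValueError):
    """Raised when data violate a model's preconditions."""


class RankDeficiencyError(InputError):
    """Design matrix is rank deficient (collinear covariates)."""


@dataclass
class ModelSpec:
    outcome: str
    family: str  # binary_logit | ordinal_logit | gaussian
    fixed_covariates: list[str]
    random_intercept: Optional[str] = None

    def __post_init__(self):
        if self.family not in ("binary_logit", "ordinal_logit", "gaussian"):
            raise InputError(f"unknown family {self.family!r}")
        if self.outcome in self.fixed_covariates:
            raise InputError("outcome must not appear among covariates")


@dataclass
class FitResult:
    """Estimates from one model fit.

    ``beta``/``beta_se`` map covariate (or dummy) names to estimates on
    the log-odds scale (minutes for gaussian). ``theta`` holds the
    ordinal thresholds. ``tau`` is the random-intercept SD (0.0 for fixed
    fits), ``sigma`` the gaussian residual SD.
    """

    outcome: str
    family: str
    beta: dict[str, float]
    beta_se: dict[str, float]
    loglik: float
    loglik_null: float
    n_obs: int
    converged: bool
    theta: Optional[np.ndarray] = None
    categories: Optional[np.ndarray] = None
    tau: float = 0.0
    sigma: Optional[float] = None
    n_groups: int = 0
    message: str = ""
    exposure: Optional[str] = None

    def odds_ratio(self, name: str, alpha: float = 0.05):
        """(OR, lower, upper) Wald interval for one coefficient."""
        from scipy.stats import norm

        b, se = self.beta[name], self.beta_se[name]
        zq = norm.ppf(1.0 - alpha / 2.0)
        return (float(np.exp(b)), float(np.exp(b - zq * se)),
                float(np.exp(b + zq * se)))


@dataclass
class CentreEffects:
    """Per-centre random-intercept summaries from a mixed fit.

    ``u_hat`` is the empirical-Bayes posterior mean of the centre
    intercept, ``se_u`` the posterior SD, ``se_fixed`` the sampling SE of
    the centre's unshrunken deviation (inverse Fisher information of the
    intercept given the fixed effects).
    """

    centre_ids: list
    u_hat: np.ndarray
    se_u: np.ndarray
    se_fixed: np.ndarray
    n_patients: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "centre_id": self.centre_ids, "u_hat": self.u_hat,
            "se_u": self.se_u, "se_fixed": self.se_fixed,
            "n_patients": self.n_patients,
        })


# ---------------------------------------------------------------------------
# design matrices

def build_design(df: pd.DataFrame, covariates: list[str]):
    """Numeric design matrix (no intercept); categoricals become dummies
    against the first sorted level."""
    cols, names = [], []
    for c in covariates:
        if c not in df.columns:
            raise InputError(f"covariate {c!r} not in data")
        s = df[c]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(pd.to_numeric(s).to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _prepare(spec: ModelSpec, cohort: pd.DataFrame):
    needed = [spec.outcome] + list(spec.fixed_covariates)
    if spec.random_intercept:
        needed.append(spec.random_intercept)
    for c in needed:
        if c not in cohort.columns:
            raise InputError(f"column {c!r} not in cohort")
    data = cohort.dropna(subset=needed)
    if len(data) == 0:
        raise InputError("no complete-case rows for this model")
    X, names = build_design(data, spec.fixed_covariates)
    if X.shape[1] and np.linalg.matrix_rank(X - X.mean(0)) < X.shape[1]:
        raise RankDeficiencyError(
            f"collinear covariates in design: {names}"
        )
    y = pd.to_numeric(data[spec.outcome]).to_numpy(dtype=float)
    if len(y) < X.shape[1] + 2:
        raise InputError("fewer observations than covariates + 2")
    groups = None
    if spec.random_intercept:
        codes, uniques = pd.factorize(data[spec.random_intercept], sort=True)
        groups = (codes, list(uniques))
    return data, y, X, names, groups


# ---------------------------------------------------------------------------
# fixed-effect fits

def _logistic_loglik(y, eta):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls_logistic(X, y, max_iter=100, tol=1e-10):
    """IRLS for logistic regression; X includes the intercept column."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    ll_old = -np.inf
    converged, message = False, ""
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(str(exc)) from exc
        ll = _logistic_loglik(y, X @ beta)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    if np.max(np.abs(eta)) > 30.0 or np.max(np.abs(beta)) > 25.0:
        converged = False
        message = "possible complete separation: diverging coefficients"
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, _logistic_loglik(y, eta), converged, message


def _gamma_to_theta(gamma):
    theta = np.empty_like(gamma)
    theta[0] = gamma[0]
    if len(gamma) > 1:
        theta[1:] = gamma[0] + np.cumsum(np.exp(gamma[1:]))
    return theta


def _theta_to_gamma(theta):
    gamma = np.empty_like(theta)
    gamma[0] = theta[0]
    if len(theta) > 1:
        gamma[1:] = np.log(np.diff(theta))
    return gamma


def _ordinal_ll_grad(theta, beta, X, kidx, K):
    """Loglik and analytic gradient (theta, beta) of the proportional-odds
    model; kidx holds 0-based category indices."""
    eta = X @ beta if X.shape[1] else np.zeros(len(kidx))
    big = 500.0
    th = np.concatenate(([-big], theta, [big]))
    su = th[kidx + 1] - eta
    sl = th[kidx] - eta
    au, al = expit(su), expit(sl)
    p = np.clip(au - al, 1e-300, None)
    ll = float(np.sum(np.log(p)))
    p = np.clip(p, 1e-120, None)  # keep p^2 representable in derivatives
    fu, fl = au * (1.0 - au), al * (1.0 - al)
    g_eta = (fl - fu) / p
    # threshold j is the upper bound for category j, lower bound for j+1;
    # category 0 has no finite lower bound (its fl is 0 there anyway)
    low = np.maximum(kidx - 1, 0)
    wl = np.where(kidx > 0, fl / p, 0.0)
    gt = (np.bincount(kidx, weights=fu / p, minlength=K)[: K - 1]
          - np.bincount(low, weights=wl, minlength=K)[: K - 1])
    gb = X.T @ g_eta if X.shape[1] else np.empty(0)
    return ll, gt, gb, (au, al, p, fu, fl)


def _ordinal_d1_d2(theta, eta, kidx):
    """First/second derivatives of the ordinal loglik wrt eta, per obs."""
    big = 500.0
    th = np.concatenate(([-big], theta, [big]))
    su, sl = th[kidx + 1] - eta, th[kidx] - eta
    au, al = expit(su), expit(sl)
    lp = np.log(np.clip(au - al, 1e-300, None))
    p = np.clip(au - al, 1e-120, None)  # p^2 must not underflow below
    fu, fl = au * (1.0 - au), al * (1.0 - al)
    d1 = (fl - fu) / p
    dnum = -fl * (1.0 - 2.0 * al) + fu * (1.0 - 2.0 * au)
    d2 = (dnum * p - (fl - fu) ** 2) / (p * p)
    return lp, d1, d2


def _fit_ordinal(X, y):
    cats, kidx = np.unique(y, return_inverse=True)
    K = len(cats)
    if K < 2:
        raise InputError("ordinal outcome has a single observed category")
    n, p = len(y), X.shape[1]
    counts = np.bincount(kidx, minlength=K)
    cum = np.clip(np.cumsum(counts)[:-1] / n, 1e-6, 1 - 1e-6)
    gamma0 = _theta_to_gamma(logit(cum))
    x0 = np.concatenate([gamma0, np.zeros(p)])

    def negll_grad(params):
        gamma, beta = params[: K - 1], params[K - 1:]
        theta = _gamma_to_theta(gamma)
        ll, gt, gb, _ = _ordinal_ll_grad(theta, beta, X, kidx, K)
        gg = np.empty(K - 1)
        gg[0] = gt.sum()
        if K > 2:
            rev = np.cumsum(gt[::-1])[::-1]
            gg[1:] = np.exp(gamma[1:]) * rev[1:]
        return -ll, -np.concatenate([gg, gb])

    res = minimize(negll_grad, x0, jac=True, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-8})
    gamma, beta = res.x[: K - 1], res.x[K - 1:]
    theta = _gamma_to_theta(gamma)
    ll = -res.fun
    converged = bool(res.success) or np.linalg.norm(res.jac) < 1e-4
    message = "" if converged else str(res.message)
    if p and np.max(np.abs(beta)) > 25.0:
        converged = False
        message = "possible complete separation: diverging coefficients"

    # SEs from the observed information in the natural (theta, beta) space
    def grad_nat(params):
        th, b = params[: K - 1], params[K - 1:]
        _, gt, gb, _ = _ordinal_ll_grad(th, b, X, kidx, K)
        return -np.concatenate([gt, gb])

    x_nat = np.concatenate([theta, beta])
    H = _num_jac(grad_nat, x_nat)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(K - 1 + p, np.nan)
    return theta, beta, se[K - 1:], se[: K - 1], ll, converged, message, cats, kidx, K


def _num_jac(f, x, h=1e-5):
    x = np.asarray(x, dtype=float)
    d = len(x)
    f0 = np.asarray(f(x))
    J = np.empty((d, len(f0)))
    for i in range(d):
        hi = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        J[i] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * hi)
    return J


def _num_hess(f, x, h=1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    hs = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i):
            ej = np.zeros(d)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def _null_loglik(family, y):
    n = len(y)
    if family == "binary_logit":
        pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        return float(y.sum() * np.log(pbar) + (n - y.sum()) * np.log(1 - pbar))
    if family == "ordinal_logit":
        _, counts = np.unique(y, return_counts=True)
        pk = counts / n
        return float(np.sum(counts * np.log(pk)))
    resid = y - y.mean()
    s2 = max(float(np.mean(resid ** 2)), 1e-300)
    return float(-0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0))


def fit_fixed(spec: ModelSpec, cohort: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fixed-effects fit (complete cases)."""
    if spec.random_intercept:
        raise InputError("spec has a random intercept; use fit_mixed")
    data, y, X, names, _ = _prepare(spec, cohort)
    n = len(y)
    ll_null = _null_loglik(spec.family, y)

    if spec.family == "binary_logit":
        if not np.isin(y, (0.0, 1.0)).all():
            raise InputError("binary outcome must be coded 0/1")
        Xi = np.column_stack([np.ones(n), X])
        beta, se, ll, conv, msg = _irls_logistic(Xi, y)
        return FitResult(
            outcome=spec.outcome, family=spec.family,
            beta=dict(zip(["intercept"] + names, beta)),
            beta_se=dict(zip(["intercept"] + names, se)),
            loglik=ll, loglik_null=ll_null, n_obs=n, converged=conv,
            message=msg,
        )
    if spec.family == "ordinal_logit":
        theta, beta, se_b, se_t, ll, conv, msg, cats, _, _ = _fit_ordinal(X, y)
        return FitResult(
            outcome=spec.outcome, family=spec.family,
            beta=dict(zip(names, beta)), beta_se=dict(zip(names, se_b)),
            theta=theta, categories=cats,
            loglik=ll, loglik_null=ll_null, n_obs=n, converged=conv,
            message=msg,
        )
    # gaussian
    Xi = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    dof = max(n - Xi.shape[1], 1)
    cov = rss / dof * np.linalg.inv(Xi.T @ Xi)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        outcome=spec.outcome, family=spec.family,
        beta=dict(zip(["intercept"] + names, beta)),
        beta_se=dict(zip(["intercept"] + names, se)),
        sigma=float(np.sqrt(sigma2)),
        loglik=float(ll), loglik_null=ll_null, n_obs=n, converged=True,
    )


# ---------------------------------------------------------------------------
# mixed models

class _BinaryFam:
    def __init__(self, y):
        self.y = y

    def ll(self, eta):
        return self.y * eta - np.logaddexp(0.0, eta)

    def d1(self, eta):
        return self.y - expit(eta)

    def d2(self, eta):
        mu = expit(eta)
        return -mu * (1.0 - mu)


class _OrdinalFam:
    def __init__(self, kidx):
        self.kidx = kidx
        self.theta = None

    def ll(self, eta):
        lp, _, _ = _ordinal_d1_d2(self.theta, eta, self.kidx)
        return lp

    def d1(self, eta):
        _, d1, _ = _ordinal_d1_d2(self.theta, eta, self.kidx)
        return d1

    def d2(self, eta):
        _, _, d2 = _ordinal_d1_d2(self.theta, eta, self.kidx)
        return d2


def _find_modes(fam, xb, g, J, tau, max_iter=60, tol=1e-10):
    """Vectorised per-centre Newton ascent of the joint log density in u."""
    tau2 = max(tau * tau, 1e-12)

    def per_centre_obj(u):
        eta = xb + u[g]
        llg = np.bincount(g, weights=fam.ll(eta), minlength=J)
        return llg - 0.5 * u * u / tau2

    u = np.zeros(J)
    f_cur = per_centre_obj(u)
    for _ in range(max_iter):
        eta = xb + u[g]
        G = np.bincount(g, weights=fam.d1(eta), minlength=J) - u / tau2
        if np.max(np.abs(G)) < tol:
            break
        H = np.bincount(g, weights=fam.d2(eta), minlength=J) - 1.0 / tau2
        step = np.clip(-G / H, -4.0, 4.0)
        t = np.ones(J)
        for _ in range(30):
            f_new = per_centre_obj(u + t * step)
            worse = f_new < f_cur - 1e-12
            if not worse.any():
                break
            t[worse] *= 0.5
        u = u + t * step
        f_cur = per_centre_obj(u)
    eta = xb + u[g]
    h = -(np.bincount(g, weights=fam.d2(eta), minlength=J) - 1.0 / tau2)
    info_fixed = -np.bincount(g, weights=fam.d2(eta), minlength=J)
    return u, h, info_fixed


def _agq_logmarg(fam, xb, g, J, tau, nodes):
    """Adaptive Gauss-Hermite log marginal likelihood per centre, plus the
    node grid and log-weights needed for empirical-Bayes summaries."""
    tau2 = max(tau * tau, 1e-12)
    uhat, h, info_fixed = _find_modes(fam, xb, g, J, tau)
    h = np.clip(h, 1e-12, None)
    sd = 1.0 / np.sqrt(h)
    z, w = hermgauss(nodes)
    a = np.empty((J, nodes))
    u_nodes = np.empty((J, nodes))
    for k in range(nodes):
        uk = uhat + _SQRT2 * sd * z[k]
        u_nodes[:, k] = uk
        eta = xb + uk[g]
        llg = np.bincount(g, weights=fam.ll(eta), minlength=J)
        lprior = -0.5 * np.log(2.0 * np.pi * tau2) - 0.5 * uk * uk / tau2
        a[:, k] = np.log(w[k]) + z[k] ** 2 + llg + lprior
    logm = logsumexp(a, axis=1) + 0.5 * np.log(2.0) + np.log(sd)
    return logm, a, u_nodes, uhat, sd, info_fixed


def _eb_summaries(a, u_nodes):
    wts = np.exp(a - logsumexp(a, axis=1, keepdims=True))
    mean = np.sum(wts * u_nodes, axis=1)
    var = np.sum(wts * (u_nodes - mean[:, None]) ** 2, axis=1)
    return mean, np.sqrt(np.clip(var, 0.0, None))


def fit_mixed(spec: ModelSpec, cohort: pd.DataFrame,
              quadrature_nodes: Optional[int] = None):
    """Random-intercept fit; returns ``(FitResult, CentreEffects)``.

    Default 15 adaptive quadrature nodes for the binary family and the
    Laplace approximation (1 node) for the ordinal family; gaussian uses
    the closed-form marginal likelihood.
    """
    if not spec.random_intercept:
        raise InputError("spec lacks a random intercept; use fit_fixed")
    data, y, X, names, groups = _prepare(spec, cohort)
    codes, uniques = groups
    J = len(uniques)
    if J < 2:
        raise InputError(
            "only one group present: fit a fixed-effects model instead"
        )
    n = len(y)
    n_per = np.bincount(codes, minlength=J)
    ll_null = _null_loglik(spec.family, y)

    if spec.family == "gaussian":
        return _fit_gaussian_mixed(spec, y, X, names, codes, uniques, n_per,
                                   ll_null)

    if spec.family == "binary_logit":
        if not np.isin(y, (0.0, 1.0)).all():
            raise InputError("binary outcome must be coded 0/1")
        nodes = 15 if quadrature_nodes is None else quadrature_nodes
        fam = _BinaryFam(y)
        fixed = fit_fixed(ModelSpec(spec.outcome, spec.family,
                                    spec.fixed_covariates), data)
        x0 = np.concatenate([
            [fixed.beta["intercept"]],
            [fixed.beta[nm] for nm in names],
            [np.log(0.3)],
        ])
        Xi = np.column_stack([np.ones(n), X])

        def negll(params):
            beta, ltau = params[:-1], params[-1]
            fam_xb = Xi @ beta
            logm, *_ = _agq_logmarg(fam, fam_xb, codes, J, np.exp(ltau), nodes)
            return -float(np.sum(logm))

        bounds = [(None, None)] * (Xi.shape[1]) + [(_LOG_TAU_MIN, _LOG_TAU_MAX)]
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7})
        beta, tau = res.x[:-1], float(np.exp(res.x[-1]))
        xb = Xi @ beta
        par_names = ["intercept"] + names
    else:  # ordinal_logit
        nodes = 1 if quadrature_nodes is None else quadrature_nodes
        cats, kidx = np.unique(y, return_inverse=True)
        K = len(cats)
        if K < 2:
            raise InputError("ordinal outcome has a single observed category")
        fam = _OrdinalFam(kidx)
        theta0, beta0, *_ = _fit_ordinal(X, y)
        x0 = np.concatenate([_theta_to_gamma(theta0), beta0, [np.log(0.3)]])

        def negll(params):
            gamma = params[: K - 1]
            beta = params[K - 1: -1]
            fam.theta = _gamma_to_theta(gamma)
            fam_xb = X @ beta if X.shape[1] else np.zeros(n)
            logm, *_ = _agq_logmarg(fam, fam_xb, codes, J,
                                    np.exp(params[-1]), nodes)
            return -float(np.sum(logm))

        bounds = ([(None, None)] * (K - 1 + X.shape[1])
                  + [(_LOG_TAU_MIN, _LOG_TAU_MAX)])
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7})
        gamma, beta = res.x[: K - 1], res.x[K - 1: -1]
        tau = float(np.exp(res.x[-1]))
        fam.theta = _gamma_to_theta(gamma)
        xb = X @ beta if X.shape[1] else np.zeros(n)
        par_names = names

    loglik = -float(res.fun)
    converged = bool(res.success)
    message = "" if converged else str(res.message)

    # empirical-Bayes summaries at the fitted parameters
    logm, a, u_nodes, uhat_mode, sd_mode, info_fixed = _agq_logmarg(
        fam, xb, codes, J, max(tau, 1e-6), max(nodes, 7)
    )
    u_hat, se_u = _eb_summaries(a, u_nodes)
    se_fixed = 1.0 / np.sqrt(np.clip(info_fixed, 1e-12, None))
    tau_hat = 0.0 if tau < _TAU_BOUNDARY else tau
    if tau_hat == 0.0:
        u_hat = np.zeros(J)
        se_u = np.zeros(J)

    # Wald SEs from the observed information of the marginal likelihood
    H = _num_hess(negll, res.x)
    try:
        cov = np.linalg.inv(0.5 * (H + H.T))
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        diag = np.full(len(res.x), np.nan)
    if spec.family == "binary_logit":
        beta_se = diag[: len(par_names)]
        theta_hat = None
    else:
        beta_se = diag[K - 1: -1]
        theta_hat = fam.theta

    fit = FitResult(
        outcome=spec.outcome, family=spec.family,
        beta=dict(zip(par_names, beta)),
        beta_se=dict(zip(par_names, beta_se)),
        theta=theta_hat,
        categories=None if spec.family == "binary_logit" else cats,
        tau=tau_hat, loglik=loglik, loglik_null=ll_null, n_obs=n,
        n_groups=J, converged=converged, message=message,
    )
    effects = CentreEffects(
        centre_ids=list(uniques), u_hat=u_hat, se_u=se_u,
        se_fixed=se_fixed, n_patients=n_per,
    )
    return fit, effects


def _fit_gaussian_mixed(spec, y, X, names, codes, uniques, n_per, ll_null):
    """Closed-form marginal likelihood with GLS-profiled fixed effects."""
    n = len(y)
    J = len(uniques)
    Xi = np.column_stack([np.ones(n), X])
    p = Xi.shape[1]
    sum_X = np.zeros((J, p))
    for j in range(p):
        sum_X[:, j] = np.bincount(codes, weights=Xi[:, j], minlength=J)
    sum_y = np.bincount(codes, weights=y, minlength=J)

    def profile(ltau, lsig):
        tau2, sig2 = np.exp(2.0 * ltau), np.exp(2.0 * lsig)
        c = tau2 / (sig2 * (sig2 + n_per * tau2))
        A = (Xi.T @ Xi) / sig2 - (sum_X * c[:, None]).T @ sum_X
        b = (Xi.T @ y) / sig2 - (sum_X * c[:, None]).T @ sum_y
        beta = np.linalg.solve(A, b)
        r = y - Xi @ beta
        sum_r = np.bincount(codes, weights=r, minlength=J)
        quad = float(r @ r) / sig2 - float(c @ (sum_r ** 2))
        logdet = float(np.sum((n_per - 1) * np.log(sig2)
                              + np.log(sig2 + n_per * tau2)))
        ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
        return ll, beta, A, sum_r

    def negll(params):
        return -profile(params[0], params[1])[0]

    s0 = np.log(max(np.std(y), 1e-3))
    res = minimize(negll, np.array([s0 - 1.0, s0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    ltau, lsig = res.x
    tau, sigma = float(np.exp(ltau)), float(np.exp(lsig))
    ll, beta, A, sum_r = profile(ltau, lsig)
    cov = np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tau2, sig2 = tau * tau, sigma * sigma
    shrink = tau2 / (sig2 + n_per * tau2)
    u_hat = shrink * sum_r
    se_u = np.sqrt(tau2 * sig2 / (sig2 + n_per * tau2))
    se_fixed = sigma / np.sqrt(n_per)
    tau_hat = 0.0 if tau < _TAU_BOUNDARY * max(sigma, 1.0) else tau
    if tau_hat == 0.0:
        u_hat = np.zeros(J)
        se_u = np.zeros(J)
    fit = FitResult(
        outcome=spec.outcome, family="gaussian",
        beta=dict(zip(["intercept"] + names, beta)),
        beta_se=dict(zip(["intercept"] + names, se)),
        tau=tau_hat, sigma=sigma, loglik=float(ll), loglik_null=ll_null,
        n_obs=n, n_groups=J, converged=bool(res.success),
        message="" if res.success else str(res.message),
    )
    effects = CentreEffects(
        centre_ids=list(uniques), u_hat=u_hat, se_u=se_u,
        se_fixed=se_fixed, n_patients=n_per,
    )
    return fit, effects


def adjusted_effect(spec: ModelSpec, cohort: pd.DataFrame,
                    adjustment_set: list[str]) -> FitResult:
    """Effect of one exposure on the outcome, adjusted for a covariate set.

    ``spec.fixed_covariates`` must name the single exposure; the fit adds
    the adjustment set and records the exposure so that
    ``result.odds_ratio(result.exposure)`` gives the Wald 95% CI.
    """
    if len(spec.fixed_covariates) != 1:
        raise InputError("spec.fixed_covariates must name exactly the exposure")
    exposure = spec.fixed_covariates[0]
    if exposure in adjustment_set:
        raise RankDeficiencyError("exposure duplicated in adjustment set")
    full = ModelSpec(spec.outcome, spec.family,
                     [exposure] + list(adjustment_set))
    fit = fit_fixed(full, cohort)
    fit.exposure = exposure
    return fit
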
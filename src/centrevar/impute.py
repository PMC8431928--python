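"""Multiple imputation by chained equations and Rubin's-rules pooling.

Each incomplete field is regressed on all other fields (outcomes
included, per the MAR working assumption) and refilled from a model
fitted to a bootstrap resample of the observed rows, which propagates
parameter uncertainty between imputations. Methods: predictive-mean
matching (continuous), logistic (binary), proportional-odds (ordinal,
including the ordered day/evening/night shift). The discharge CPC score
is imputed consistently with observed mortality: a patient recorded as
dead gets CPC 5, a survivor draws from categories 0-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as t_dist

from .glmm import (FitResult, InputError, _fit_ordinal, _irls_logistic,
                   build_design)

#: default imputation method per known cohort field
_DEFAULT_METHODS = {
    "age": "pmm", "time_to_als": "pmm", "charlson": "pmm",
    "sex": "logistic", "rrs_reported": "logistic", "witnessed": "logistic",
    "weekend": "logistic", "shockable": "logistic", "mortality": "logistic",
    "pre_mrs": "ordinal", "pre_cpc": "ordinal", "cpc_discharge": "ordinal",
    "shift": "ordinal",
}

_SHIFT_ORDER = ["day", "evening", "night"]


@dataclass
class ImputationSet:
    m: int
    completed: list[pd.DataFrame]
    methods: dict[str, str]


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one coefficient across m imputations."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def ci(self, alpha: float = 0.05):
        q = t_dist.ppf(1.0 - alpha / 2.0, self.df) if np.isfinite(self.df) \
            else 1.959963984540054
        return (self.estimate - q * self.se, self.estimate + q * self.se)


def _method_for(col: str, s: pd.Series) -> str:
    if col in _DEFAULT_METHODS:
        return _DEFAULT_METHODS[col]
    if s.dtype.kind in "OUS":
        return "ordinal"
    vals = s.dropna().unique()
    if set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        return "logistic"
    if len(vals) <= 8 and np.allclose(np.asarray(vals, float) % 1, 0):
        return "ordinal"
    return "pmm"


def _predictor_matrix(df: pd.DataFrame, target: str):
    preds = [c for c in df.columns if c not in (target, "centre_id")]
    X, _ = build_design(df, preds)
    return np.column_stack([np.ones(len(df)), X])


def impute(cohort: pd.DataFrame, m: int = 5, seed: int = 0,
           n_iter: int = 10, methods: dict[str, str] | None = None
           ) -> ImputationSet:
    """Produce ``m`` completed copies of ``cohort`` by chained equations."""
    if m < 1:
        raise InputError("m must be positive")
    incomplete = [c for c in cohort.columns if cohort[c].isna().any()]
    for c in incomplete:
        if cohort[c].isna().all():
            raise InputError(f"field {c!r} is entirely missing")
    use_methods = {}
    for c in incomplete:
        use_methods[c] = (methods or {}).get(c, _method_for(c, cohort[c]))
    if not incomplete:
        return ImputationSet(m=m, completed=[cohort.copy() for _ in range(m)],
                             methods=use_methods)

    order = sorted(incomplete, key=lambda c: cohort[c].isna().sum())
    masks = {c: cohort[c].isna().to_numpy() for c in incomplete}
    streams = np.random.SeedSequence(seed).spawn(m)
    completed = []
    for chain in range(m):
        rng = np.random.default_rng(streams[chain])
        df = cohort.copy()
        for c in incomplete:  # initialise from the observed margin
            obs = df[c].dropna().to_numpy()
            df.loc[masks[c], c] = rng.choice(obs, size=masks[c].sum())
        for _ in range(n_iter):
            for c in order:
                _impute_field(df, cohort, c, masks[c], use_methods[c], rng)
        completed.append(df)
    return ImputationSet(m=m, completed=completed, methods=use_methods)


def _impute_field(df, original, col, mis, method, rng):
    obs = ~mis
    X = _predictor_matrix(df, col)
    if method == "ordinal" and df[col].dtype.kind in "OUS":
        y_obs, values = _encode_ordered(original.loc[obs, col])
    else:
        y_obs = pd.to_numeric(original.loc[obs, col]).to_numpy(dtype=float)
        values = None
    if np.ptp(y_obs) == 0:  # constant observed margin
        df.loc[mis, col] = original.loc[obs, col].iloc[0]
        return
    boot = rng.choice(np.flatnonzero(obs), size=int(obs.sum()), replace=True)
    Xo, Xm, Xb, yb = X[obs], X[mis], X[boot], None

    if method == "pmm":
        yo = y_obs
        yb = pd.to_numeric(df[col]).to_numpy(dtype=float)[boot]
        beta_hat = _ridge_lstsq(Xo, yo)
        beta_star = _ridge_lstsq(Xb, yb)
        pred_obs = Xo @ beta_hat
        pred_mis = Xm @ beta_star
        df.loc[mis, col] = _pmm_draw(pred_obs, pred_mis, yo, rng, k=5)
        return

    if method == "logistic":
        yb = pd.to_numeric(df[col]).to_numpy(dtype=float)[boot]
        try:
            beta, *_ = _irls_logistic(Xb, yb)
        except Exception:
            beta, *_ = _irls_logistic(Xo, y_obs)
        p = expit(Xm @ beta)
        df.loc[mis, col] = (rng.random(len(p)) < p).astype(float)
        return

    # ordinal via proportional odds on a bootstrap refit
    yb_raw = df[col].to_numpy()[boot]
    if values is not None:
        lut = {v: i for i, v in enumerate(values)}
        yb = np.array([lut[v] for v in yb_raw], dtype=float)
        yo = np.array([lut[v] for v in original.loc[obs, col]], dtype=float)
    else:
        yb = np.asarray(yb_raw, dtype=float)
        yo = y_obs
    try:
        theta, beta, *_rest = _fit_ordinal(Xb[:, 1:], yb)
        cats = _rest[5]
    except Exception:
        theta, beta, *_rest = _fit_ordinal(Xo[:, 1:], yo)
        cats = _rest[5]
    eta = Xm[:, 1:] @ beta if Xm.shape[1] > 1 else np.zeros(Xm.shape[0])
    cum = expit(theta[None, :] - eta[:, None])
    probs = np.diff(np.concatenate(
        [np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1), axis=1)
    draws_idx = _sample_rows(probs, rng)
    draws = cats[draws_idx]
    if col == "cpc_discharge" and "mortality" in df.columns:
        draws = _constrain_cpc(draws, probs, cats,
                               df.loc[mis, "mortality"].to_numpy(), rng)
    if values is not None:
        df.loc[mis, col] = np.asarray(values, dtype=object)[
            draws.astype(int)]
    else:
        df.loc[mis, col] = draws.astype(float)


def _encode_ordered(s: pd.Series):
    vals = [v for v in _SHIFT_ORDER if v in set(s)] or sorted(s.unique())
    lut = {v: i for i, v in enumerate(vals)}
    return np.array([lut[v] for v in s], dtype=float), vals


def _ridge_lstsq(X, y, lam=1e-8):
    A = X.T @ X + lam * np.eye(X.shape[1])
    return np.linalg.solve(A, X.T @ y)


def _pmm_draw(pred_obs, pred_mis, y_obs, rng, k=5):
    """Type-1 predictive-mean matching: draw one of the k nearest donors."""
    out = np.empty(len(pred_mis))
    kk = min(k, len(y_obs))
    for i, pm in enumerate(pred_mis):
        idx = np.argpartition(np.abs(pred_obs - pm), kk - 1)[:kk]
        out[i] = y_obs[idx[rng.integers(kk)]]
    return out


def _sample_rows(probs, rng):
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1][:, None]
    return np.sum(rng.random(len(probs))[:, None] > cum[:, :-1], axis=1)


def _constrain_cpc(draws, probs, cats, mortality, rng):
    """Keep the death/CPC-5 equivalence when mortality is observed."""
    draws = draws.astype(float).copy()
    dead = mortality == 1
    draws[dead] = 5.0
    alive = np.flatnonzero(~dead)
    if len(alive) and 5.0 in cats:
        k5 = int(np.where(cats == 5.0)[0][0])
        p = probs[alive].copy()
        p[:, k5] = 0.0
        empty = p.sum(axis=1) <= 0
        p[empty, max(k5 - 1, 0)] = 1.0  # survivor with all mass on death
        draws[alive] = cats[_sample_rows(p, rng)]
    return draws


def pool(fits: list[FitResult]) -> dict[str, PooledEstimate]:
    """Rubin's rules across ``m`` fits of one model specification."""
    if len(fits) < 2:
        raise InputError("pooling requires at least two fits")
    keys = list(fits[0].beta)
    for f in fits[1:]:
        if list(f.beta) != keys or f.family != fits[0].family \
                or f.outcome != fits[0].outcome:
            raise InputError("fits do not share a model specification")
    m = len(fits)
    out = {}
    for k in keys:
        est = np.array([f.beta[k] for f in fits])
        ses = np.array([f.beta_se[k] for f in fits])
        out[k] = pool_scalar(est, ses ** 2)
    return out


def pool_scalar(estimates, variances) -> PooledEstimate:
    """Rubin's rules for one quantity given per-imputation variances."""
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    m = len(estimates)
    qbar = float(estimates.mean())
    w = float(variances.mean())
    b = float(estimates.var(ddof=1)) if m > 1 else 0.0
    total = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = np.inf
    return PooledEstimate(estimate=qbar, within_var=w, between_var=b,
                          total_var=total, df=float(df), m=m)
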
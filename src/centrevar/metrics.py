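"""Heterogeneity metrics for provider profiling.

* Median odds ratio (MOR): the median odds ratio between two randomly
  drawn centres (higher over lower). For centre intercepts
  u ~ Normal(0, tau^2) this is exp(sqrt(2) * tau * Phi^-1(0.75)).
* Rankability: the share of between-centre variation not attributable to
  chance, tau^2 / (tau^2 + aggregate(se_j^2)) with the squared sampling
  SEs of the centre estimates aggregated by their median (or mean).
* Nagelkerke R^2: Cox-Snell R^2 rescaled by its attainable maximum.
* Caterpillar data: ordered, anonymised shrunken centre effects with
  95% intervals, adjusted next to unadjusted.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.stats import norm

from .glmm import CentreEffects, InputError

#: sqrt(2) * Phi^-1(0.75); MOR = exp(_MOR_FACTOR * tau)
_MOR_FACTOR = float(np.sqrt(2.0) * norm.ppf(0.75))


def median_odds_ratio(tau: float) -> float:
    """MOR for a centre random-intercept SD ``tau`` (logit scale)."""
    if tau < 0:
        raise InputError("tau must be non-negative")
    return float(np.exp(_MOR_FACTOR * tau))


def rankability(tau: float, se_centres, aggregate: str = "median") -> float:
    """Fraction of between-centre variance not attributable to chance."""
    if tau < 0:
        raise InputError("tau must be non-negative")
    se = np.asarray(list(se_centres), dtype=float)
    if se.size == 0:
        raise InputError("need at least one centre standard error")
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    agg = np.median if aggregate == "median" else np.mean
    s2 = float(agg(se ** 2))
    t2 = tau * tau
    if t2 == 0.0:
        return 0.0
    return float(t2 / (t2 + s2))


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and null log-likelihoods."""
    if n < 1:
        raise InputError("n must be at least 1")
    if loglik_model < loglik_null - 1e-6:
        raise InputError("model loglik below null loglik")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0.0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def percent_change_mor(mor_unadjusted: float, mor_adjusted: float) -> int:
    """Percent decrease of the MOR on adjustment, to the nearest integer."""
    if mor_unadjusted < 1.0 or mor_adjusted < 1.0:
        raise InputError("MOR values must be >= 1")
    pct = 100.0 * (mor_unadjusted - mor_adjusted) / mor_unadjusted
    return int(round(pct))


def anonymise_centre(centre_id, salt: str = "centrevar") -> str:
    """Stable anonymised label for a centre identifier."""
    digest = hashlib.sha1(f"{salt}:{centre_id}".encode()).hexdigest()
    return f"H-{digest[:6]}"


def build_caterpillar(effects_unadj: CentreEffects,
                      effects_adj: CentreEffects,
                      anonymise: bool = True) -> dict:
    """Per-centre shrunken effects with 95% intervals, ordered by the
    unadjusted estimate, for caterpillar plotting."""
    ids_u = list(effects_unadj.centre_ids)
    ids_a = list(effects_adj.centre_ids)
    if set(ids_u) != set(ids_a):
        raise InputError("unadjusted and adjusted centre sets differ")
    pos_a = {c: i for i, c in enumerate(ids_a)}
    order = np.argsort(effects_unadj.u_hat, kind="stable")
    centres = []
    for rank, i in enumerate(order):
        cid = ids_u[i]
        j = pos_a[cid]
        entry = {
            "label": anonymise_centre(cid) if anonymise else str(cid),
            "rank": rank + 1,
            "n_patients": int(effects_unadj.n_patients[i]),
            "unadjusted": _interval(effects_unadj, i),
            "adjusted": _interval(effects_adj, j),
        }
        centres.append(entry)
    return {"centres": centres}


def _interval(eff: CentreEffects, i: int) -> dict:
    u, se = float(eff.u_hat[i]), float(eff.se_u[i])
    return {"estimate": u, "lower": u - 1.96 * se, "upper": u + 1.96 * se}
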
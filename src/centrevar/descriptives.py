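"""Univariable group comparisons: Mann-Whitney U, chi-square, Fisher exact.

Continuous variables are summarised as median [IQR] and compared with the
Mann-Whitney U test (exact enumeration for combined n <= 12 without ties,
tie-corrected normal approximation otherwise). Categorical variables are
summarised as count (%) and compared with the chi-square test, falling
back to Fisher's exact test (probability-ordering two-sided convention;
Monte-Carlo with fixed margins for tables beyond 2x2) whenever any
expected cell count is below 5. Percentages are always recomputed from
raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .glmm import InputError

#: cohort fields summarised as median [IQR] by default
DEFAULT_CONTINUOUS = ("age", "charlson", "time_to_als")


@dataclass
class GroupComparison:
    variable: str
    kind: str                  # continuous | categorical
    test: str                  # mann_whitney | chi_square | fisher
    p_value: float
    group_stats: dict = field(default_factory=dict)
    statistic: float | None = None


def mann_whitney(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U statistic of ``x`` versus ``y`` with its p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability ordering)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise InputError("counts must be non-negative integers")
        t = t.astype(int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(t, logfact_margins, logfact_n):
    return logfact_margins - logfact_n - gammaln(t + 1.0).sum()


def fisher_exact_rxc(table, n_mc: int = 100_000, seed: int = 0):
    """Monte-Carlo Fisher exact test for an RxC table.

    Samples ``n_mc`` tables with the observed margins (Patefield
    algorithm) and returns ``(p, mc_se)`` where p is the fraction of
    tables at most as probable as the observed one, with the +1
    correction for the observed table itself.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise InputError("table must be at least 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise InputError("counts must be non-negative integers")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return 1.0, 0.0
    lf_m = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
    lf_n = gammaln(t.sum() + 1.0)
    lp_obs = _log_table_prob(t, lf_m, lf_n)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows.astype(int), cols.astype(int))
    samples = dist.rvs(n_mc, random_state=rng)
    lp = lf_m - lf_n - gammaln(samples + 1.0).sum(axis=(1, 2))
    hits = int(np.sum(lp <= lp_obs + 1e-9))
    p = (hits + 1.0) / (n_mc + 1.0)
    se = float(np.sqrt(p * (1.0 - p) / n_mc))
    return float(p), se


def _crosstab(a: pd.Series, b: pd.Series) -> np.ndarray:
    ct = pd.crosstab(a, b)
    return ct.to_numpy()


def compare_groups(cohort: pd.DataFrame, group_field: str,
                   variables: list[str],
                   continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
                   n_mc: int = 100_000, seed: int = 0
                   ) -> list[GroupComparison]:
    """Table-2-style comparison of two groups on a list of variables."""
    g = cohort[group_field]
    if g.isna().any():
        raise InputError(f"group field {group_field!r} has missing values")
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise InputError("group field must be binary")
    if (g == levels[0]).sum() == 0 or (g == levels[1]).sum() == 0:
        raise InputError("both groups must be non-empty")

    out = []
    for var in variables:
        s = cohort[var]
        mask = s.notna()
        if var in continuous:
            xs = [pd.to_numeric(s[mask & (g == lev)]).to_numpy(float)
                  for lev in levels]
            u, p = mann_whitney(xs[0], xs[1])
            gstats = {
                str(lev): {
                    "n": int(len(x)),
                    "median": float(np.median(x)) if len(x) else None,
                    "q1": float(np.percentile(x, 25)) if len(x) else None,
                    "q3": float(np.percentile(x, 75)) if len(x) else None,
                } for lev, x in zip(levels, xs)
            }
            out.append(GroupComparison(var, "continuous", "mann_whitney",
                                       p, gstats, u))
            continue
        ct = _crosstab(s[mask], g[mask])
        cats = sorted(s[mask].unique())
        gstats = {}
        for j, lev in enumerate(levels):
            tot = int(ct[:, j].sum())
            gstats[str(lev)] = {
                "n": tot,
                "counts": {str(c): int(ct[i, j]) for i, c in enumerate(cats)},
                "percents": {str(c): round(100.0 * ct[i, j] / tot, 1)
                             if tot else None for i, c in enumerate(cats)},
            }
        ct_use = ct[ct.sum(axis=1) > 0]
        if ct_use.shape[0] < 2:
            out.append(GroupComparison(var, "categorical", "fisher", 1.0,
                                       gstats))
            continue
        expected = (ct_use.sum(axis=1)[:, None] * ct_use.sum(axis=0)[None, :]
                    / ct_use.sum())
        if (expected < 5).any():
            if ct_use.shape == (2, 2):
                p = fisher_exact_2x2(ct_use)
            else:
                p, _ = fisher_exact_rxc(ct_use, n_mc=n_mc, seed=seed)
            test, statv = "fisher", None
        else:
            chi2, p, _, _ = stats.chi2_contingency(ct_use, correction=False)
            test, statv = "chi_square", float(chi2)
        out.append(GroupComparison(var, "categorical", test, float(p),
                                   gstats, statv))
    return out
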
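"""Univariable tests against enumeration oracles and scipy cross-checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from centrevar import (InputError, compare_groups, fisher_exact_2x2,
                       fisher_exact_rxc, mann_whitney)


def enumerate_fisher_2x2(table):
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins that are at most as probable."""
    t = np.asarray(table)
    r0, r1 = t.sum(axis=1)
    c0 = t.sum(axis=0)[0]
    n = t.sum()

    def logp(a):
        rest = np.array([[a, r0 - a], [c0 - a, r1 - (c0 - a)]])
        if (rest < 0).any():
            return None
        return (gammaln(r0 + 1) + gammaln(r1 + 1) + gammaln(c0 + 1)
                + gammaln(n - c0 + 1) - gammaln(n + 1)
                - gammaln(rest + 1.0).sum())

    lp_obs = logp(t[0, 0])
    total = 0.0
    for a in range(0, min(r0, c0) + 1):
        lp = logp(a)
        if lp is not None and lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return total


@pytest.mark.parametrize("table,expected", [
    ([[3, 1], [1, 3]], 0.485714285714),
    ([[0, 5], [5, 0]], 2.0 / 252.0),
    ([[8, 2], [1, 5]], None),
    ([[4, 4], [3, 9]], None),
])
def test_fisher_2x2_matches_enumeration(table, expected):
    p = fisher_exact_2x2(table)
    assert p == pytest.approx(enumerate_fisher_2x2(table), abs=1e-10)
    if expected is not None:
        assert p == pytest.approx(expected, abs=1e-9)


def test_fisher_2x2_degenerate_margin_is_one():
    assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0
    assert fisher_exact_2x2([[2, 0], [5, 0]]) == 1.0


def test_fisher_2x2_label_permutation_invariant():
    t = np.array([[7, 2], [3, 9]])
    p = fisher_exact_2x2(t)
    assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
    assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)
    assert fisher_exact_2x2(t.T) == pytest.approx(p)


def enumerate_fisher_rxc(table):
    """Full enumeration over all non-negative tables with fixed margins."""
    t = np.asarray(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    lf_m = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
    lf_n = gammaln(t.sum() + 1.0)

    def logp(tt):
        return lf_m - lf_n - gammaln(np.asarray(tt) + 1.0).sum()

    lp_obs = logp(t)
    total = 0.0
    # enumerate first row cells; remaining row determined by margins (2xC)
    assert t.shape[0] == 2
    ranges = [range(int(min(rows[0], c)) + 1) for c in cols]
    for first in itertools.product(*ranges):
        if sum(first) != rows[0]:
            continue
        second = cols - np.array(first)
        if (second < 0).any():
            continue
        lp = logp(np.vstack([first, second]))
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return total


def test_fisher_rxc_monte_carlo_matches_enumeration():
    table = [[5, 9, 4], [8, 2, 7]]
    exact = enumerate_fisher_rxc(table)
    p, se = fisher_exact_rxc(table, n_mc=40_000, seed=12)
    assert abs(p - exact) < 3.0 * max(se, 1e-6)


def test_fisher_rxc_extreme_alternative():
    table = [[60, 5, 5], [5, 5, 60]]
    p, _ = fisher_exact_rxc(table, n_mc=100_000, seed=3)
    assert p < 0.001


def test_fisher_rxc_degenerate_single_row_mass():
    p, se = fisher_exact_rxc([[0, 0, 0], [3, 4, 5]], n_mc=1000, seed=0)
    assert p == 1.0


def test_mann_whitney_exact_enumeration_case():
    u, p_less = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
    assert u == 0.0
    assert p_less == pytest.approx(1.0 / 20.0)
    _, p_two = mann_whitney([1, 2, 3], [4, 5, 6])
    assert p_two == pytest.approx(2.0 / 20.0)


def test_mann_whitney_identical_samples_and_power():
    _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert p == 1.0
    rng = np.random.default_rng(1)
    _, p2 = mann_whitney(rng.normal(0, 1, 300), rng.normal(1.5, 1, 300))
    assert p2 < 0.001
    with pytest.raises(InputError):
        mann_whitney([], [1.0])


def test_compare_groups_table2_style(study_cohort):
    cohort, _, _ = study_cohort
    comps = compare_groups(cohort, "mortality",
                           ["age", "charlson", "shockable", "shift"],
                           seed=1)
    by_var = {c.variable: c for c in comps}
    assert by_var["age"].test == "mann_whitney"
    # percentages recompute from counts and sum to 100 within a group
    shock = by_var["shockable"].group_stats
    for lev, gs in shock.items():
        assert sum(gs["counts"].values()) == gs["n"]
        assert sum(gs["percents"].values()) == pytest.approx(100.0, abs=0.2)
        for cat, cnt in gs["counts"].items():
            assert gs["percents"][cat] == pytest.approx(
                100.0 * cnt / gs["n"], abs=0.051)
    assert 0.0 <= by_var["shift"].p_value <= 1.0


def test_compare_groups_constant_variable_fisher_p_one():
    df = pd.DataFrame({"g": [0, 0, 1, 1] * 5, "v": [1] * 20})
    comp = compare_groups(df, "g", ["v"], continuous=())[0]
    assert comp.test == "fisher"
    assert comp.p_value == 1.0


def test_compare_groups_small_cells_use_fisher():
    df = pd.DataFrame({"g": [0] * 10 + [1] * 10,
                       "v": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0,
                             1, 1, 1, 0, 0, 0, 0, 0, 0, 0]})
    comp = compare_groups(df, "g", ["v"], continuous=())[0]
    assert comp.test == "fisher"


def test_compare_groups_requires_binary_group(study_cohort):
    cohort, _, _ = study_cohort
    with pytest.raises(InputError):
        compare_groups(cohort, "shift", ["age"])
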
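"""Generator correctness: bookkeeping, determinism, moment recovery, MAR."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import binom, chi2_contingency

from centrevar import (ConfigurationError, SimConfig, generate_cohort,
                       inject_missingness)

UNIFORM_THETA = [float(logit(k / 6)) for k in range(1, 6)]


def test_bookkeeping_rows_and_centre_counts():
    cfg = SimConfig(n_centres=12, patients_per_centre=58)
    cohort, centres, _ = generate_cohort(cfg)
    assert len(cohort) == 696
    assert cohort["centre_id"].nunique() == 12
    assert (centres["n_patients"] == 58).all()
    assert set(cohort["centre_id"]) == set(centres["centre_id"])


def test_default_config_matches_study_scale(study_cohort):
    cohort, centres, _ = study_cohort
    assert len(cohort) == 701
    assert cohort["centre_id"].nunique() == 12
    assert int(np.median(centres["n_patients"])) == 49


def test_generator_is_deterministic():
    a, ca, ta = generate_cohort(SimConfig(seed=123))
    b, cb, tb = generate_cohort(SimConfig(seed=123))
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ca, cb)
    assert ta == tb
    c, _, _ = generate_cohort(SimConfig(seed=124))
    assert not a.equals(c)


def test_mortality_is_top_cpc_category(study_cohort):
    cohort, _, _ = study_cohort
    assert ((cohort["mortality"] == 1) == (cohort["cpc_discharge"] == 5)).all()


def test_ordinal_fields_within_ranges(study_cohort):
    cohort, _, _ = study_cohort
    assert cohort["cpc_discharge"].between(0, 5).all()
    assert cohort["pre_cpc"].between(0, 4).all()
    assert cohort["pre_mrs"].between(0, 5).all()
    assert (cohort["time_to_als"] >= 0).all()
    assert set(cohort["shift"]) <= {"day", "evening", "night"}


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(theta=[1.0, 0.9, 1.2, 1.3, 1.4])
    with pytest.raises((ConfigurationError, ValueError)):
        SimConfig(n_centres=0)
    with pytest.raises(ConfigurationError):
        SimConfig(missing_rates={"cpc_discharge": 1.5})
    with pytest.raises(ConfigurationError):
        SimConfig(n_centres=3, patients_per_centre=[10, 10])


def test_no_centre_effect_gives_homogeneous_mortality():
    """With tau=0 and no case-mix effects, per-centre mortality differs
    only by binomial noise: the chi-square homogeneity test should be
    non-significant in at least 90% of seeds."""
    nonsig = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = SimConfig(n_centres=12, patients_per_centre=50,
                        tau_outcome=0.0, beta={}, theta=UNIFORM_THETA,
                        missing_rates={}, seed=seed)
        cohort, _, _ = generate_cohort(cfg)
        tab = pd.crosstab(cohort["centre_id"], cohort["mortality"])
        _, p, _, _ = chi2_contingency(tab)
        nonsig += p > 0.05
    assert nonsig >= 0.9 * n_seeds


def test_between_centre_logit_sd_recovers_tau():
    """Monte-Carlo moment check: with no case-mix trend, the SD of the
    per-centre logit mortality rates recovers tau (plus a known binomial
    noise floor) at 200 centres x 500 patients."""
    cfg = SimConfig(n_centres=200, patients_per_centre=500, tau_outcome=0.3,
                    beta={}, missing_rates={}, seed=42)
    cohort, _, truth = generate_cohort(cfg)
    rates = cohort.groupby("centre_id")["mortality"].mean()
    lo = logit(rates.clip(1e-6, 1 - 1e-6))
    p = cohort["mortality"].mean()
    noise_var = 1.0 / (500 * p * (1 - p))
    tau_emp = np.sqrt(max(np.var(lo, ddof=1) - noise_var, 0.0))
    assert abs(tau_emp - 0.3) < 0.05


def test_zero_rates_leave_table_untouched(study_cohort):
    cohort, _, _ = study_cohort
    cfg = SimConfig(missing_rates={"cpc_discharge": 0.0, "age": 0.0}, seed=11)
    out = inject_missingness(cohort, cfg)
    pd.testing.assert_frame_equal(out, cohort)


def test_input_table_never_mutated(study_cohort):
    cohort, _, _ = study_cohort
    before = cohort.copy()
    inject_missingness(cohort, SimConfig(seed=11))
    pd.testing.assert_frame_equal(cohort, before)


def test_missingness_rate_calibration():
    """A 1.7% rate on the CPC score of a 701-patient cohort should leave
    a missing count consistent with Binomial(701, 0.017) across seeds."""
    counts = []
    for seed in range(40):
        cfg = SimConfig(missing_rates={"cpc_discharge": 0.017}, seed=seed)
        cohort, _, _ = generate_cohort(cfg)
        out = inject_missingness(cohort, cfg)
        counts.append(int(out["cpc_discharge"].isna().sum()))
    lo, hi = binom.ppf([0.005, 0.995], 701, 0.017)
    assert lo <= np.mean(counts) <= hi
    # expectation 11.9 of the study configuration
    assert abs(np.mean(counts) - 701 * 0.017) < 3.0


def test_mar_mechanism_recovers_positive_driver_slope():
    """Missingness increasing in age must be recoverable by a logistic
    regression of the missingness indicator on age."""
    import statsmodels.api as sm

    cfg = SimConfig(n_centres=12, patients_per_centre=400,
                    missing_rates={"cpc_discharge": 0.2}, mar_driver="age",
                    mar_slope=1.0, seed=3)
    cohort, _, _ = generate_cohort(cfg)
    out = inject_missingness(cohort, cfg)
    ind = out["cpc_discharge"].isna().astype(int)
    X = sm.add_constant(cohort["age"])
    res = sm.Logit(ind, X).fit(disp=0)
    assert res.params["age"] > 0
    assert res.pvalues["age"] < 1e-6
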
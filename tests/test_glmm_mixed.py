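"""Random-intercept models: quadrature oracles, recovery, shrinkage, lme4."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from centrevar import InputError, ModelSpec, SimConfig, adjusted_effect, \
    fit_fixed, fit_mixed, generate_cohort
from conftest import make_binary_cluster_data


def dense_binary_marginal_loglik(df, beta0, beta1, tau, n_grid=10_001):
    """Trapezoid integration of the logistic random-intercept likelihood."""
    ll = 0.0
    half = max(10.0 * tau, 1.0)
    ug = np.linspace(-half, half, n_grid)
    dens = np.exp(-0.5 * (ug / tau) ** 2) / np.sqrt(2 * np.pi * tau ** 2)
    for _, grp in df.groupby("centre"):
        eta = (beta0 + beta1 * grp["x"].to_numpy())[:, None] + ug[None, :]
        y = grp["y"].to_numpy()[:, None]
        pl = np.prod(np.where(y == 1, expit(eta), expit(-eta)), axis=0)
        ll += np.log(np.trapezoid(pl * dens, ug))
    return ll


def test_binary_marginal_loglik_matches_dense_integration():
    df, _ = make_binary_cluster_data(J=3, nj=10, tau=1.2, seed=21)
    fit, _ = fit_mixed(ModelSpec("y", "binary_logit", ["x"], "centre"), df,
                       quadrature_nodes=15)
    assert fit.tau > 0.05  # interior solution so the oracle grid resolves it
    oracle = dense_binary_marginal_loglik(
        df, fit.beta["intercept"], fit.beta["x"], fit.tau)
    assert abs(oracle - fit.loglik) < 1e-3


def test_ordinal_laplace_close_to_dense_integration():
    """The one-node (Laplace) ordinal fit evaluated with many adaptive
    nodes must agree with dense integration at the same parameters."""
    rng = np.random.default_rng(8)
    J, nj = 4, 30
    u = rng.normal(0, 0.8, J)
    g = np.repeat(np.arange(J), nj)
    x = rng.normal(size=J * nj)
    eta = 0.6 * x + u[g]
    theta = np.array([-0.8, 0.4, 1.5])
    cum = expit(theta[None, :] - eta[:, None])
    y = np.sum(rng.random(J * nj)[:, None] > cum, axis=1).astype(float)
    df = pd.DataFrame({"y": y, "x": x, "centre": g.astype(str)})

    fit15, _ = fit_mixed(ModelSpec("y", "ordinal_logit", ["x"], "centre"),
                         df, quadrature_nodes=15)
    assert fit15.tau > 0.05
    # dense integration at the fitted parameters
    ll = 0.0
    ug = np.linspace(-10 * fit15.tau, 10 * fit15.tau, 10_001)
    dens = np.exp(-0.5 * (ug / fit15.tau) ** 2) / np.sqrt(
        2 * np.pi * fit15.tau ** 2)
    th = np.concatenate([[-500.0], fit15.theta, [500.0]])
    for j in range(J):
        sel = g == j
        e = (fit15.beta["x"] * x[sel])[:, None] + ug[None, :]
        k = y[sel].astype(int)
        p = expit(th[k + 1][:, None] - e) - expit(th[k][:, None] - e)
        ll += np.log(np.trapezoid(np.prod(p, axis=0) * dens, ug))
    assert abs(ll - fit15.loglik) < 1e-3


def test_binary_mixed_matches_lme4_glmer():
    """Independent oracle: lme4's glmer with 15-node adaptive quadrature."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not on PATH; lme4 oracle unavailable")
    df, _ = make_binary_cluster_data(J=8, nj=25, tau=1.0, seed=7)
    fit, _ = fit_mixed(ModelSpec("y", "binary_logit", ["x"], "centre"), df,
                       quadrature_nodes=15)
    import tempfile
    with tempfile.TemporaryDirectory() as td:
        path = f"{td}/d.csv"
        df.to_csv(path, index=False)
        script = (
            f'd <- read.csv("{path}");'
            'suppressMessages(library(lme4));'
            'm <- glmer(y ~ x + (1|centre), data=d, family=binomial, nAGQ=15);'
            'cat(fixef(m)["(Intercept)"], fixef(m)["x"], '
            'sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
    vals = [float(v) for v in out.stdout.strip().splitlines()[-4:]]
    assert fit.beta["intercept"] == pytest.approx(vals[0], abs=2e-3)
    assert fit.beta["x"] == pytest.approx(vals[1], abs=2e-3)
    assert fit.tau == pytest.approx(vals[2], abs=2e-3)
    assert fit.loglik == pytest.approx(vals[3], abs=1e-3)


def test_tau_zero_boundary_recovers_fixed_fit():
    # large per-centre n keeps the sampling noise of tau-hat well below
    # the 0.05 check (per-centre logit variance ~ 1/(nj p(1-p)))
    df, _ = make_binary_cluster_data(J=50, nj=1000, tau=0.0, seed=13)
    fit, effects = fit_mixed(ModelSpec("y", "binary_logit", ["x"], "centre"),
                             df)
    fixed = fit_fixed(ModelSpec("y", "binary_logit", ["x"]), df)
    assert fit.tau < 0.05
    for k in ("intercept", "x"):
        assert abs(fit.beta[k] - fixed.beta[k]) < 2 * fixed.beta_se[k]
    assert fit.loglik >= fixed.loglik - 1e-6  # fixed model nested at tau=0


def test_tau_recovery_against_generator_truth():
    df, u = make_binary_cluster_data(J=400, nj=120, tau=0.3, seed=17)
    fit, _ = fit_mixed(ModelSpec("y", "binary_logit", ["x"], "centre"), df)
    assert abs(fit.tau - 0.3) < 0.03
    assert abs(fit.beta["x"] - 0.7) < 0.03


def test_gaussian_mixed_matches_statsmodels_mixedlm(study_cohort):
    import statsmodels.formula.api as smf

    cohort, _, _ = study_cohort
    fit, effects = fit_mixed(
        ModelSpec("time_to_als", "gaussian", ["age"], "centre_id"), cohort)
    ref = smf.mixedlm("time_to_als ~ age", cohort,
                      groups="centre_id").fit(reml=False)
    assert fit.tau == pytest.approx(np.sqrt(ref.cov_re.iloc[0, 0]), abs=1e-3)
    assert fit.sigma == pytest.approx(np.sqrt(ref.scale), abs=1e-3)
    assert fit.beta["age"] == pytest.approx(ref.params["age"], abs=1e-5)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
    # EB means match the fitted random effects
    re = np.array([ref.random_effects[c].iloc[0] for c in effects.centre_ids])
    assert np.allclose(effects.u_hat, re, atol=1e-3)


def test_shrinkage_is_monotone_in_group_size():
    """Two centres with identical raw deviations: the smaller one must be
    pulled harder towards zero."""
    rng = np.random.default_rng(3)
    rows = []
    for cid, n, shift in (("small", 12, 2.0), ("big", 120, 2.0),
                          ("ref1", 120, 0.0), ("ref2", 120, 0.0)):
        y = rng.normal(shift, 1.0, n)
        y = y - y.mean() + shift  # exact raw deviation
        rows.append(pd.DataFrame({"y": y, "centre": cid}))
    df = pd.concat(rows, ignore_index=True)
    fit, eff = fit_mixed(ModelSpec("y", "gaussian", [], "centre"), df)
    d = dict(zip(eff.centre_ids, eff.u_hat))
    assert abs(d["small"]) < abs(d["big"])
    raw = df.groupby("centre")["y"].mean() - fit.beta["intercept"]
    for cid in eff.centre_ids:
        assert abs(d[cid]) <= abs(raw[cid]) + 1e-9


def test_eb_effects_centre_near_zero_weighted_by_precision(study_cohort):
    cohort, _, _ = study_cohort
    fit, eff = fit_mixed(
        ModelSpec("mortality", "binary_logit", ["age"], "centre_id"), cohort)
    if fit.tau > 0:
        w = 1.0 / np.clip(eff.se_u ** 2, 1e-12, None)
        centre_mean = float(np.sum(w * eff.u_hat) / np.sum(w))
        assert abs(centre_mean) < 0.05


def test_single_group_instructs_fixed_model():
    df = pd.DataFrame({"y": [0.0, 1, 0, 1, 1, 0], "x": np.arange(6.0),
                       "centre": "only"})
    with pytest.raises(InputError, match="fixed"):
        fit_mixed(ModelSpec("y", "binary_logit", ["x"], "centre"), df)


def test_null_exposure_wald_coverage():
    """With a null exposure, the adjusted 95% CI should cover OR = 1 in
    roughly 95% of simulations."""
    rng = np.random.default_rng(0)
    n, hits, n_sim = 250, 0, 200
    for _ in range(n_sim):
        x = rng.normal(size=n)
        w = rng.integers(0, 2, n).astype(float)
        eta = 0.5 * w  # exposure truly null
        theta = np.array([-0.5, 0.5, 1.5])
        cum = expit(theta[None, :] - eta[:, None])
        y = np.sum(rng.random(n)[:, None] > cum, axis=1).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        fit = adjusted_effect(ModelSpec("y", "ordinal_logit", ["x"]), df,
                              ["w"])
        _, lo, hi = fit.odds_ratio("x")
        hits += lo <= 1.0 <= hi
    assert 0.90 * n_sim <= hits <= 0.99 * n_sim


def test_known_exposure_or_recovered_within_ci():
    """Generator truth OR = 1.5 should fall inside the Wald CI in at
    least 90% of seeds."""
    hits, n_seeds = 0, 20
    b = np.log(1.5)
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        n = 400
        x = rng.normal(size=n)
        w = rng.normal(size=n)
        eta = b * x + 0.4 * w
        theta = np.array([-0.5, 0.5, 1.5])
        cum = expit(theta[None, :] - eta[:, None])
        y = np.sum(rng.random(n)[:, None] > cum, axis=1).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        fit = adjusted_effect(ModelSpec("y", "ordinal_logit", ["x"]), df,
                              ["w"])
        _, lo, hi = fit.odds_ratio("x")
        hits += lo <= 1.5 <= hi
    assert hits >= 0.9 * n_seeds
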
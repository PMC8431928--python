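"""Synthetic multicentre IHCA cohorts with known between-centre variance.

One latent proportional-odds process generates the ordinal discharge CPC
score; in-hospital mortality is its top category (CPC 5 = death), so the
invariant ``mortality == 1  <=>  cpc_discharge == 5`` holds by
construction. Centre heterogeneity enters as Normal(0, tau^2) random
intercepts on the logit scale (separately for the outcome process and for
RRS reporting) and as a Normal(0, sigma^2) shift of the centre mean time
to ALS. Missingness is injected afterwards under a logistic
missing-at-random (MAR) mechanism steered by one observed covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import ConfigurationError, SimConfig

#: column order of a cohort table
COHORT_COLUMNS = [
    "centre_id", "age", "sex", "charlson", "pre_mrs", "pre_cpc",
    "rrs_reported", "time_to_als", "witnessed", "weekend", "shift",
    "shockable", "location", "mortality", "cpc_discharge",
]

CENTRE_COLUMNS = [
    "centre_id", "n_patients", "training_twice_yearly", "intensivist_24_7",
    "als_physician_24_7",
]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams from one master seed.

    Fixed spawn order (centres, patients, missingness) so adding a later
    stage never perturbs earlier draws.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "centres": np.random.default_rng(children[0]),
        "patients": np.random.default_rng(children[1]),
        "missingness": np.random.default_rng(children[2]),
    }


def _draw_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(probs) / np.sum(probs)
    return np.searchsorted(cum, rng.random(n), side="right")


def generate_cohort(config: SimConfig):
    """Generate a cohort, its centre table, and the ground-truth map.

    Returns ``(cohort, centres, truth)`` where ``truth`` records every
    parameter and per-centre effect used, for recovery tests.
    """
    if config.n_centres < 1:
        raise ConfigurationError("need at least one centre")
    sizes = np.asarray(config.centre_sizes())
    n = int(sizes.sum())
    rng_c = _streams(config.seed)["centres"]
    rng_p = _streams(config.seed)["patients"]
    m = config.marginals

    width = max(2, len(str(config.n_centres)))
    ids = np.array([f"C{j + 1:0{width}d}" for j in range(config.n_centres)])

    u_outcome = rng_c.normal(0.0, config.tau_outcome, config.n_centres)
    u_rrs = rng_c.normal(0.0, config.tau_process, config.n_centres)
    als_shift = rng_c.normal(0.0, config.sigma_als_centre, config.n_centres)
    training = (rng_c.random(config.n_centres) < m.training_twice_p).astype(int)
    intensivist = (rng_c.random(config.n_centres) < m.intensivist_24_7_p).astype(int)
    als_phys = (rng_c.random(config.n_centres) < m.als_physician_24_7_p).astype(int)

    g = np.repeat(np.arange(config.n_centres), sizes)

    lo, hi = m.age_bounds
    age = rng_p.normal(m.age_mean, m.age_sd, n)
    bad = (age < lo) | (age > hi)
    while bad.any():  # truncation by redraw
        age[bad] = rng_p.normal(m.age_mean, m.age_sd, bad.sum())
        bad = (age < lo) | (age > hi)
    age = np.round(age, 1)
    sex = (rng_p.random(n) < m.female_p).astype(int)
    charlson = np.minimum(rng_p.poisson(m.charlson_mean, n), m.charlson_max)
    pre_mrs = _draw_categorical(rng_p, np.asarray(m.pre_mrs_probs), n)
    pre_cpc = _draw_categorical(rng_p, np.asarray(m.pre_cpc_probs), n)
    witnessed = (rng_p.random(n) < m.witnessed_p).astype(int)
    weekend = (rng_p.random(n) < m.weekend_p).astype(int)
    shift_names = list(m.shift_probs)
    shift = np.take(shift_names,
                    _draw_categorical(rng_p, np.asarray(list(m.shift_probs.values())), n))
    shockable = (rng_p.random(n) < m.shockable_p).astype(int)
    loc_names = list(m.location_probs)
    location = np.take(loc_names,
                       _draw_categorical(rng_p, np.asarray(list(m.location_probs.values())), n))

    covariates = {
        "age": age, "sex": sex, "charlson": charlson, "pre_mrs": pre_mrs,
        "pre_cpc": pre_cpc, "witnessed": witnessed, "weekend": weekend,
        "shockable": shockable,
    }
    eta = np.zeros(n)
    for name, b in config.beta.items():
        if name not in covariates:
            raise ConfigurationError(f"beta refers to unknown covariate {name!r}")
        eta = eta + b * covariates[name]
    eta = eta + u_outcome[g]

    # ordinal draw: P(Y <= k) = expit(theta_k - eta), categories 0..5
    theta = np.asarray(config.theta)
    cum = expit(theta[None, :] - eta[:, None])  # (n, 5) increasing per row
    cpc = np.sum(rng_p.random(n)[:, None] > cum, axis=1)  # 0..5
    mortality = (cpc == 5).astype(int)

    rrs = (rng_p.random(n) < expit(m.rrs_base_logit + u_rrs[g])).astype(int)
    tta = np.maximum(
        0.0, m.als_mean + als_shift[g] + rng_p.normal(0.0, m.als_patient_sd, n)
    )
    tta = np.round(tta, 1)

    cohort = pd.DataFrame({
        "centre_id": ids[g],
        "age": age,
        "sex": sex,
        "charlson": charlson.astype(int),
        "pre_mrs": pre_mrs.astype(float),
        "pre_cpc": pre_cpc.astype(float),
        "rrs_reported": rrs,
        "time_to_als": tta,
        "witnessed": witnessed,
        "weekend": weekend,
        "shift": shift,
        "shockable": shockable,
        "location": location,
        "mortality": mortality,
        "cpc_discharge": cpc.astype(float),
    }, columns=COHORT_COLUMNS)

    centres = pd.DataFrame({
        "centre_id": ids,
        "n_patients": sizes,
        "training_twice_yearly": training,
        "intensivist_24_7": intensivist,
        "als_physician_24_7": als_phys,
    }, columns=CENTRE_COLUMNS)

    truth = {
        "tau_outcome": config.tau_outcome,
        "tau_process": config.tau_process,
        "sigma_als_centre": config.sigma_als_centre,
        "beta": dict(config.beta),
        "theta": list(config.theta),
        "u_outcome": dict(zip(ids.tolist(), u_outcome.tolist())),
        "u_rrs": dict(zip(ids.tolist(), u_rrs.tolist())),
        "als_shift": dict(zip(ids.tolist(), als_shift.tolist())),
        "rrs_base_logit": m.rrs_base_logit,
        "als_mean": m.als_mean,
        "als_patient_sd": m.als_patient_sd,
        "seed": config.seed,
    }
    return cohort, centres, truth


def _mar_intercept(rate: float, z: np.ndarray, slope: float) -> float:
    """Intercept a such that mean(expit(a + slope*z)) == rate."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    if slope == 0.0 or np.allclose(z, z[0]):
        return float(logit(rate))

    def f(a):
        return expit(a + slope * z).mean() - rate

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def inject_missingness(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Blank selected fields under a logistic MAR mechanism.

    The missingness probability of each configured field is
    ``expit(a_f + slope * z)`` with ``z`` the standardised ``mar_driver``
    column and ``a_f`` calibrated so the expected rate matches
    ``missing_rates[f]``. The input table is never modified.
    """
    for field, rate in config.missing_rates.items():
        if field not in cohort.columns:
            raise ConfigurationError(f"missing_rates field {field!r} not in cohort")
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {field} outside [0, 1]")
    if config.mar_driver not in cohort.columns:
        raise ConfigurationError(f"mar_driver {config.mar_driver!r} not in cohort")

    out = cohort.copy()
    rng = _streams(config.seed)["missingness"]
    driver = pd.to_numeric(cohort[config.mar_driver]).to_numpy(dtype=float)
    sd = driver.std()
    z = (driver - driver.mean()) / (sd if sd > 0 else 1.0)
    for field, rate in config.missing_rates.items():
        if rate == 0.0:
            continue
        a = _mar_intercept(rate, z, config.mar_slope)
        p = expit(a + config.mar_slope * z)
        mask = rng.random(len(out)) < p
        if out[field].dtype.kind in "iub":
            out[field] = out[field].astype(float)
        col = out[field].copy()
        col[mask] = np.nan
        out[field] = col
    return out
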
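import numpy as np
import pandas as pd
import pytest

from centrevar import SimConfig, generate_cohort, inject_missingness


@pytest.fixture(scope="session")
def study_cohort():
    """One study-scale synthetic cohort (701 patients, 12 centres)."""
    cfg = SimConfig(seed=11)
    cohort, centres, truth = generate_cohort(cfg)
    return cohort, centres, truth


@pytest.fixture(scope="session")
def study_cohort_missing(study_cohort):
    cohort, centres, truth = study_cohort
    return inject_missingness(cohort, SimConfig(seed=11)), centres, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_binary_cluster_data(J, nj, tau, beta=0.7, intercept=-0.3, seed=0):
    """Logistic random-intercept data with one standard-normal covariate."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, tau, J)
    g = np.repeat(np.arange(J), nj)
    x = rng.normal(0.0, 1.0, J * nj)
    y = (rng.random(J * nj) < expit(intercept + beta * x + u[g])).astype(int)
    df = pd.DataFrame({
        "y": y, "x": x, "centre": np.array([f"C{j:03d}" for j in range(J)])[g],
    })
    return df, u
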
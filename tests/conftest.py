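"""Shared fixtures and independent numerical oracles.

The grid-integration oracle below evaluates the person-level marginal
likelihood by dense 2-D trapezoid quadrature over the standardized
random-effect plane; it shares no code with the package's Gauss–Hermite
path and serves as the brute-force reference for likelihood tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

import twopart_intake as tpi


def grid_person_loglik(params, person_df, half=8.0, n=1601) -> float:
    """Brute-force marginal log-likelihood of one participant by trapezoid
    integration over the standardized (z1, z2) plane."""
    s1, s2, se = params.sigma_u1, params.sigma_u2, params.sigma_e
    rho = params.rho
    z = np.linspace(-half, half, n)
    w = norm.pdf(z)
    w[0] *= 0.5
    w[-1] *= 0.5
    w *= z[1] - z[0]
    u1 = s1 * z[:, None] + 0.0 * z[None, :]
    u2 = s2 * (rho * z[:, None] + np.sqrt(1 - rho**2) * z[None, :])
    X = np.column_stack([np.ones(len(person_df)), person_df["exposure"],
                         person_df["sex"],
                         person_df["exposure"] * person_df["sex"]])
    eta1 = X @ params.beta_prob
    eta2 = X @ params.beta_amt
    grams = person_df["grams"].to_numpy(float)
    total = np.zeros_like(u1)
    for j, g in enumerate(grams):
        p = expit(eta1[j] + u1)
        if g > 0:
            total += (np.log(p)
                      - 0.5 * ((np.log(g) - eta2[j] - u2) / se) ** 2
                      - np.log(g * se * np.sqrt(2 * np.pi)))
        else:
            total += np.log1p(-p)
    return float(np.log((np.exp(total) * w[:, None] * w[None, :]).sum()))


def simulate_one_group(truth, n_participants, seed, exposure_mean=92.0,
                       exposure_sd=75.0, n_days=2):
    """One-age-group dataset for a single food-group truth."""
    rng = np.random.default_rng(seed)
    s2 = np.log1p((exposure_sd / exposure_mean) ** 2)
    exposure = rng.lognormal(np.log(exposure_mean) - 0.5 * s2, np.sqrt(s2),
                             n_participants)
    parts = pd.DataFrame({
        "participant_id": np.arange(n_participants),
        "age_group": "19-50", "age": 30,
        "sex": rng.integers(0, 2, n_participants),
        "exposure": exposure,
    })
    return tpi.generate_recalls(parts, [truth], n_days=n_days, seed=seed)


#: Well-identified reference truth used across estimation tests: moderate
#: consumption probability, correlated random effects.
REFERENCE_TRUTH = dict(
    label="reference",
    beta_prob=[-1.0, 0.012, 0.4, -0.006],
    beta_amt=[3.2, -0.004, 0.25, 0.003],
    sigma_u1=1.0, sigma_u2=0.8, rho=0.5, sigma_e=0.6,
)

REFERENCE_NATURAL = {
    "beta_prob_const": -1.0, "beta_prob_exposure": 0.012,
    "beta_prob_sex": 0.4, "beta_prob_exposure_x_sex": -0.006,
    "beta_amt_const": 3.2, "beta_amt_exposure": -0.004,
    "beta_amt_sex": 0.25, "beta_amt_exposure_x_sex": 0.003,
    "sigma_u1": 1.0, "sigma_u2": 0.8, "cov_u12": 0.4, "sigma_e": 0.6,
}


@pytest.fixture(scope="session")
def reference_truth():
    return tpi.FoodGroupTruth(**REFERENCE_TRUTH)


@pytest.fixture(scope="session")
def small_study():
    """Small multi-age, multi-food-group study with default truths."""
    cfg = tpi.PopulationConfig(n_participants=60, seed=42)
    return tpi.generate_study(cfg)


@pytest.fixture(scope="session")
def reference_fit(reference_truth):
    """A converged correlated fit on one synthetic group (n=400)."""
    ds = simulate_one_group(reference_truth, 400, seed=7)
    return tpi.fit(ds.data, variant="correlated")
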
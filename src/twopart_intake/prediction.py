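"""Monte-Carlo predicted intake at covariate profiles.

The predicted intake for a covariate profile (a meat-quartile mean, a sex)
is the average over simulated person-level random effects of the product

    probability_v * amount_v
      = expit(x'beta_prob + u1_v) * exp(x'beta_amt + u2_v + 0.5 sigma_e^2),

with (u1_v, u2_v) drawn from the fitted random-effect covariance (jointly
for the correlated variant, independently for the uncorrelated one) and the
log-normal mean back-transformation adding half the day-to-day variance.
Averaging the per-draw *product* — not the product of averages — is what
lets the correlation between the two parts show up in the predicted intake.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._rng import substream
from .model import FitResult, TwoPartParams, ParameterizationError

__all__ = [
    "CovariateProfile",
    "PredictionResult",
    "draw_random_effects",
    "predict_intake",
    "probability_to_weekly_days",
    "relative_difference",
]

_EXP_GUARD = 300.0  # exponent clip: keeps amounts (and their squares) finite


@dataclass(frozen=True)
class CovariateProfile:
    """One prediction point: exposure (g/2,000 kcal) and sex (0=f, 1=m)."""

    exposure: float
    sex: int

    def __post_init__(self):
        if self.exposure < 0:
            raise ValueError("exposure must be non-negative")
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0 (female) or 1 (male)")

    def design_row(self) -> np.ndarray:
        return np.array([1.0, self.exposure, self.sex,
                         self.exposure * self.sex])


@dataclass
class PredictionResult:
    probability: float   # mean predicted day-level consumption probability
    amount: float        # mean predicted amount among consumers (g/2,000 kcal)
    intake: float        # mean of per-draw probability*amount (g/2,000 kcal)
    n_draws: int
    mc_se: float         # Monte-Carlo standard error of `intake`
    seed: int | None = None


def _split(fit) -> tuple[TwoPartParams, bool, str]:
    # Duck-typed: FitResult (or any fit-like object) carries params/variant/
    # parts; a bare TwoPartParams is treated as a correlated two-part truth.
    if hasattr(fit, "variant"):
        return fit.params, fit.variant == "correlated", fit.parts
    return fit, True, "both"


def draw_random_effects(fit: FitResult | TwoPartParams, n_draws: int,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        standard_normals: np.ndarray | None = None
                        ) -> np.ndarray:
    """Paired (u1, u2) draws from the fitted random-effect distribution.

    Correlated variant: joint bivariate normal with the estimated covariance.
    Uncorrelated variant: independent normal draws for the two parts.
    ``standard_normals`` (shape (n_draws, 2)) allows common random numbers
    across profiles of one food group.
    """
    params, correlated, _ = _split(fit)
    s1, s2 = params.sigma_u1, params.sigma_u2
    if correlated:
        rho = params.rho
        if abs(rho) > 1:
            raise ParameterizationError("non-PSD random-effect covariance")
    else:
        rho = 0.0
    if standard_normals is None:
        if rng is None:
            rng = substream(0 if seed is None else seed, "random-effects")
        standard_normals = rng.standard_normal((n_draws, 2))
    z = standard_normals[:n_draws]
    u1 = s1 * z[:, 0]
    u2 = s2 * (rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1])
    return np.column_stack([u1, u2])


def predict_intake(fit: FitResult | TwoPartParams, profile: CovariateProfile,
                   n_draws: int = 10_000, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   standard_normals: np.ndarray | None = None
                   ) -> PredictionResult:
    """Monte-Carlo predicted intake at one covariate profile.

    Per draw v the log odds and log amount are formed from the fixed effects
    plus the drawn random effects; the odds are back-transformed with
    odds/(1+odds), the amount with exp(. + 0.5 sigma_e^2); the intake is the
    average of the per-draw probability*amount products.  With zero
    random-effect variances every draw coincides and the result is exact.
    """
    params, correlated, parts = _split(fit)
    u = draw_random_effects(fit, n_draws, seed=seed, rng=rng,
                            standard_normals=standard_normals)
    x = profile.design_row()

    if parts in ("both", "probability"):
        log_odds = float(x @ params.beta_prob) + u[:, 0]
        p = expit(log_odds)  # equals odds/(1+odds), evaluated stably
    else:
        p = np.ones(n_draws)

    if parts in ("both", "amount"):
        log_amount = (float(x @ params.beta_amt) + u[:, 1]
                      + 0.5 * params.sigma_e**2)
        if np.any(log_amount > _EXP_GUARD):
            warnings.warn("extreme linear predictor in amount part; "
                          "clipping before exponentiation")
            log_amount = np.minimum(log_amount, _EXP_GUARD)
        a = np.exp(log_amount)
    else:
        a = np.full(n_draws, np.nan)

    product = p * a
    intake = float(np.mean(product))
    mc_se = (float(np.std(product, ddof=1) / np.sqrt(n_draws))
             if n_draws > 1 else 0.0)
    return PredictionResult(
        probability=float(np.mean(p)), amount=float(np.mean(a)),
        intake=intake, n_draws=n_draws, mc_se=mc_se, seed=seed)


def probability_to_weekly_days(probability):
    """Convert a daily consumption probability to expected days per week
    (7 * probability); e.g. probability 0.45 means about 3.15 days/week."""
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must lie in [0, 1]")
    out = 7.0 * p
    return float(out) if out.ndim == 0 else out


def relative_difference(pred_q4: float, pred_q1: float,
                        group_mean: float) -> float:
    """Relative difference in predicted intake between the highest and
    lowest meat quartile, scaled by the age-sex group's mean intake:
    (pred_q4 - pred_q1) / group_mean.  Negative values mean the food group
    is eaten *more* where meat consumption is low."""
    if not group_mean > 0:
        raise ValueError("group mean intake must be positive")
    return (pred_q4 - pred_q1) / group_mean
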
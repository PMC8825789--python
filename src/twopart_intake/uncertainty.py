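"""Parametric-bootstrap percentile intervals for predicted intakes.

Estimation uncertainty is propagated by redrawing whole parameter vectors
from the multivariate normal approximation (estimates, estimated covariance)
of the fitted model — correlated or uncorrelated, whichever was used — and
rerunning the Monte-Carlo prediction for each replicate.  The 2.5 and 97.5
empirical percentiles of the replicate intakes form the 95% interval.

Parameter vectors are drawn on the unconstrained scale (log SDs, atanh
correlation), where the normal approximation is defensible and where every
draw maps back to a valid parameter set (positive variances, |rho| < 1), so
no replicate has to be discarded for invalid variance parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .model import FitResult, ParameterizationError
from .prediction import CovariateProfile, predict_intake

__all__ = ["IntervalResult", "bootstrap_ci"]


@dataclass
class IntervalResult:
    point: float    # predicted intake at the estimates
    lower: float    # 2.5 percentile over bootstrap replicates
    upper: float    # 97.5 percentile
    n_boot: int
    n_dropped: int
    seed: int | None
    replicates: np.ndarray | None = None  # kept only on request


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor; tolerates tiny negative eigenvalues, rejects
    genuinely non-PSD covariance."""
    cov = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        tol = 1e-8 * max(1.0, float(np.abs(vals).max()))
        if vals.min() < -tol:
            raise ParameterizationError(
                f"parameter covariance is not PSD (min eigenvalue {vals.min():.3e})")
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def bootstrap_ci(fit: FitResult, profile: CovariateProfile,
                 n_boot: int = 1000, n_draws: int = 10_000,
                 seed: int = 0, keep_replicates: bool = False
                 ) -> IntervalResult:
    """95% parametric-bootstrap percentile interval for the predicted intake.

    Draws ``n_boot`` parameter vectors from N(theta_hat, cov) on the
    unconstrained scale, maps each back to valid parameters, and repeats the
    full Monte-Carlo prediction with *fresh* random-effect draws per
    replicate.  Replicates yielding non-finite intakes are dropped (an error
    is raised if more than 1% are).  Percentiles use the same interpolated
    (n+1)p order-statistic rule as the quartile machinery.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit with a valid "
                         "parameter covariance")
    theta = np.asarray(fit.theta, float)
    L = _psd_factor(np.asarray(fit.cov_unconstrained, float))

    rng = substream(seed, "bootstrap")
    thetas = theta[None, :] + rng.standard_normal((n_boot, len(theta))) @ L.T

    point = predict_intake(fit, profile, n_draws=n_draws,
                           rng=substream(seed, "bootstrap-point")).intake

    intakes = np.empty(n_boot)
    with warnings.catch_warnings():
        # extreme parameter draws may trip the overflow clip; replicate
        # predictions remain finite, so no need to spam per-replicate warnings
        warnings.simplefilter("ignore", UserWarning)
        for b in range(n_boot):
            try:
                params_b = fit.params_from_theta(thetas[b])
                pred = predict_intake(
                    _ReplicateView(fit, params_b), profile, n_draws=n_draws,
                    rng=substream(seed, "bootstrap-replicate", b))
                intakes[b] = pred.intake
            except (FloatingPointError, ParameterizationError, ValueError):
                intakes[b] = np.nan
    finite = np.isfinite(intakes)
    n_dropped = int(n_boot - finite.sum())
    if n_dropped > 0.01 * n_boot:
        raise RuntimeError(
            f"{n_dropped}/{n_boot} bootstrap replicates failed to predict")
    kept = intakes[finite]
    lower, upper = np.percentile(kept, [2.5, 97.5], method="weibull")
    return IntervalResult(point=float(point), lower=float(lower),
                          upper=float(upper), n_boot=n_boot,
                          n_dropped=n_dropped, seed=seed,
                          replicates=kept if keep_replicates else None)


class _ReplicateView:
    """Minimal fit-like view so replicate predictions honour the fitted
    variant and parts flags while carrying replicate parameters."""

    def __init__(self, fit: FitResult, params):
        self.params = params
        self.variant = fit.variant
        self.parts = fit.parts
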
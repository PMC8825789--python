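"""Monte-Carlo prediction: random-effect draws, back-transformation,
oracle agreement and the derived summary statistics."""
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import twopart_intake as tpi
from twopart_intake.model import TwoPartParams


def make_params(s1=1.0, s2=0.8, rho=0.5, se=0.6):
    return TwoPartParams([-1.0, 0.012, 0.4, -0.006], [3.2, -0.004, 0.25, 0.003],
                         s1, s2, rho * s1 * s2, se)


def uncorrelated_view(params):
    return SimpleNamespace(params=params, variant="uncorrelated", parts="both")


class TestDrawRandomEffects:
    def test_zero_variance_draws_are_degenerate(self):
        u = tpi.draw_random_effects(make_params(s1=0, s2=0, rho=0), 100, seed=1)
        assert np.all(u == 0.0)

    def test_correlated_draws_match_target_correlation(self):
        u = tpi.draw_random_effects(make_params(rho=0.9), 10_000, seed=2)
        assert abs(np.corrcoef(u.T)[0, 1] - 0.9) < 0.01

    def test_uncorrelated_variant_breaks_correlation(self):
        view = uncorrelated_view(make_params(rho=0.9))
        u = tpi.draw_random_effects(view, 10_000, seed=3)
        assert abs(np.corrcoef(u.T)[0, 1]) < 0.03

    def test_marginal_sds_match(self):
        u = tpi.draw_random_effects(make_params(), 20_000, seed=4)
        assert u[:, 0].std() == pytest.approx(1.0, abs=0.03)
        assert u[:, 1].std() == pytest.approx(0.8, abs=0.03)


class TestPredictIntake:
    profile = tpi.CovariateProfile(90.0, 1)

    def test_zero_variance_is_exact(self):
        params = make_params(s1=0, s2=0, rho=0, se=0.6)
        pred = tpi.predict_intake(params, self.profile, n_draws=50, seed=5)
        x = self.profile.design_row()
        p = expit(x @ params.beta_prob)
        a = np.exp(x @ params.beta_amt + 0.5 * 0.6**2)
        assert pred.probability == pytest.approx(p, rel=1e-12)
        assert pred.amount == pytest.approx(a, rel=1e-12)
        assert pred.intake == pytest.approx(p * a, rel=1e-12)
        assert pred.mc_se == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_numeric_integration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(3):
            truth = tpi.FoodGroupTruth(
                "t", rng.normal(0, 0.5, 4) * [1, 0.01, 1, 0.01],
                rng.normal([3, 0, 0, 0], [0.5, 0.003, 0.2, 0.003]),
                rng.uniform(0.3, 1.2), rng.uniform(0.3, 1.0),
                rng.uniform(-0.7, 0.7), rng.uniform(0.3, 0.8))
            _, _, analytic = tpi.true_marginal_intake(truth, 90.0, 1)
            params = TwoPartParams(truth.beta_prob, truth.beta_amt,
                                   truth.sigma_u1, truth.sigma_u2,
                                   truth.cov_u12, truth.sigma_e)
            pred = tpi.predict_intake(params, self.profile, n_draws=10_000,
                                      seed=int(rng.integers(2**30)))
            assert abs(pred.intake - analytic) <= 3 * pred.mc_se

    def test_seed_stability_at_default_draws(self):
        params = make_params()
        a = tpi.predict_intake(params, self.profile, n_draws=10_000, seed=7)
        b = tpi.predict_intake(params, self.profile, n_draws=10_000, seed=8)
        assert abs(a.intake - b.intake) <= 4 * max(a.mc_se, b.mc_se)

    def test_fixed_seed_is_bit_reproducible(self):
        params = make_params()
        a = tpi.predict_intake(params, self.profile, n_draws=2000, seed=9)
        b = tpi.predict_intake(params, self.profile, n_draws=2000, seed=9)
        assert (a.probability, a.amount, a.intake) == (b.probability, b.amount, b.intake)

    def test_monotone_in_part_intercepts(self):
        base = make_params()
        shift_p = make_params()
        shift_p.beta_prob = base.beta_prob + np.array([0.5, 0, 0, 0])
        shift_a = make_params()
        shift_a.beta_amt = base.beta_amt + np.array([0.5, 0, 0, 0])
        kw = dict(n_draws=4000, seed=10)
        b = tpi.predict_intake(base, self.profile, **kw)
        p = tpi.predict_intake(shift_p, self.profile, **kw)
        a = tpi.predict_intake(shift_a, self.profile, **kw)
        assert p.probability > b.probability
        assert a.amount > b.amount and a.intake > b.intake

    def test_positive_correlation_lifts_intake_above_product(self):
        params = make_params(rho=0.8, s1=1.0, s2=1.0)
        pred = tpi.predict_intake(params, self.profile, n_draws=50_000, seed=11)
        assert pred.intake > pred.probability * pred.amount


class TestSummaries:
    def test_weekly_days_reference_conversion(self):
        assert tpi.probability_to_weekly_days(0.45) == pytest.approx(3.15)
        assert tpi.probability_to_weekly_days(0.0) == 0.0
        assert tpi.probability_to_weekly_days(1.0) == 7.0

    @given(p=st.floats(min_value=0, max_value=1, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_weekly_days_bounds(self, p):
        assert 0.0 <= tpi.probability_to_weekly_days(p) <= 7.0

    def test_weekly_days_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tpi.probability_to_weekly_days(1.2)

    def test_relative_difference_reference_values(self):
        assert tpi.relative_difference(4.22, 49.97, 19.50) == pytest.approx(
            -2.346, abs=5e-4)
        assert tpi.relative_difference(3.0, 3.0, 10.0) == 0.0
        assert tpi.relative_difference(2 * 7.0, 7.0, 7.0) == pytest.approx(1.0)

    def test_relative_difference_rejects_zero_mean(self):
        with pytest.raises(ValueError):
            tpi.relative_difference(1.0, 2.0, 0.0)


class TestProfile:
    def test_design_row(self):
        row = tpi.CovariateProfile(80.0, 1).design_row()
        np.testing.assert_allclose(row, [1.0, 80.0, 1.0, 80.0])

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            tpi.CovariateProfile(-1.0, 0)
        with pytest.raises(ValueError):
            tpi.CovariateProfile(10.0, 2)
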
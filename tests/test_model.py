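"""Likelihood correctness, estimation behaviour and variant selection."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import check_grad
from scipy.special import log_expit
from scipy.stats import norm

import twopart_intake as tpi
from twopart_intake.model import (_ModelData, _nll_grad, _Parameterization,
                                  SeparationError, TwoPartParams,
                                  dataset_loglik)

from conftest import grid_person_loglik, simulate_one_group


def random_instance(rng, n_pers=None):
    """Small model-random instance: truth params + data generated from them."""
    n_pers = n_pers or int(rng.integers(2, 6))
    truth = tpi.FoodGroupTruth(
        "t",
        [rng.normal(0, 0.8), rng.normal(0, 0.3), rng.normal(0, 0.3), rng.normal(0, 0.1)],
        [rng.normal(1, 0.8), rng.normal(0, 0.3), rng.normal(0, 0.3), rng.normal(0, 0.1)],
        rng.uniform(0.2, 1.2), rng.uniform(0.2, 1.2),
        rng.uniform(-0.8, 0.8), rng.uniform(0.3, 1.0))
    parts = pd.DataFrame({
        "participant_id": np.arange(n_pers), "age_group": "19-50", "age": 30,
        "sex": rng.integers(0, 2, n_pers), "exposure": rng.uniform(0, 2, n_pers)})
    ds = tpi.generate_recalls(parts, [truth], n_days=2,
                              seed=int(rng.integers(2**30)))
    params = TwoPartParams(truth.beta_prob, truth.beta_amt, truth.sigma_u1,
                           truth.sigma_u2, truth.cov_u12, truth.sigma_e)
    return params, ds.data


class TestPersonLoglik:
    def test_degenerate_zero_variance_single_day(self):
        params = TwoPartParams([0.4, 0.1, 0, 0], [3.0, 0.01, 0, 0],
                               0.0, 0.0, 0.0, 0.5)
        df = pd.DataFrame([{"participant_id": 0, "day": 1, "exposure": 2.0,
                            "sex": 0, "grams": 25.0}])
        eta1 = 0.4 + 0.1 * 2.0
        eta2 = 3.0 + 0.01 * 2.0
        expected = (log_expit(eta1)
                    + norm.logpdf(np.log(25.0), eta2, 0.5) - np.log(25.0))
        for adaptive in (True, False):
            got = tpi.person_loglik(params, df, adaptive=adaptive)
            assert got == pytest.approx(float(expected), abs=1e-9)

    def test_quadrature_matches_grid_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            params, df = random_instance(rng)
            gh = sum(tpi.person_loglik(params, df[df["participant_id"] == i])
                     for i in df["participant_id"].unique())
            grid = sum(grid_person_loglik(params, df[df["participant_id"] == i])
                       for i in df["participant_id"].unique())
            assert gh == pytest.approx(grid, abs=1e-6)

    def test_amount_parameters_irrelevant_when_never_consumed(self):
        df = pd.DataFrame([
            {"participant_id": 0, "day": d, "exposure": 1.0, "sex": 1, "grams": 0.0}
            for d in (1, 2)])
        base = TwoPartParams([-0.5, 0.2, 0.1, 0], [3.0, 0, 0, 0], 0.8, 0.6, 0.2, 0.5)
        other = TwoPartParams([-0.5, 0.2, 0.1, 0], [9.0, 1, -1, 2], 0.8, 0.6, 0.2, 1.5)
        assert tpi.person_loglik(base, df) == pytest.approx(
            tpi.person_loglik(other, df), abs=1e-10)

    def test_multiple_participants_rejected(self):
        df = pd.DataFrame([
            {"participant_id": i, "day": 1, "exposure": 1.0, "sex": 0, "grams": 0.0}
            for i in (0, 1)])
        params = TwoPartParams([0, 0, 0, 0], [1, 0, 0, 0], 0.5, 0.5, 0.0, 0.5)
        with pytest.raises(ValueError, match="single participant"):
            tpi.person_loglik(params, df)


class TestGradient:
    @pytest.mark.parametrize("correlated", [True, False])
    def test_analytic_gradient_matches_finite_differences(self, correlated):
        rng = np.random.default_rng(21)
        _, df = random_instance(rng, n_pers=5)
        par = _Parameterization(correlated=correlated, nodes=9)
        md = _ModelData(df)
        theta = np.r_[rng.normal(0, 0.4, 8), rng.normal(-0.3, 0.2, par.n_free - 8)]
        err = check_grad(lambda t: _nll_grad(t, md, par)[0],
                         lambda t: _nll_grad(t, md, par)[1],
                         theta, epsilon=1e-6)
        scale = np.linalg.norm(_nll_grad(theta, md, par)[1]) + 1.0
        assert err / scale < 1e-4


class TestParameterValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(tpi.ParameterizationError):
            TwoPartParams([0, 0, 0, 0], [0, 0, 0, 0], -0.1, 0.5, 0.0, 0.5)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(tpi.ParameterizationError):
            TwoPartParams([0, 0, 0, 0], [0, 0, 0, 0], 0.5, 0.5, 0.3, 0.5)

    def test_pack_unpack_roundtrip(self):
        par = _Parameterization(nodes=5)
        p = TwoPartParams([0.1, -0.2, 0.3, 0.0], [2.0, 0.1, -0.1, 0.05],
                          0.7, 1.2, -0.3, 0.45)
        q = par.unpack(par.pack(p))
        np.testing.assert_allclose(q.beta_prob, p.beta_prob)
        np.testing.assert_allclose(
            [q.sigma_u1, q.sigma_u2, q.cov_u12, q.sigma_e],
            [p.sigma_u1, p.sigma_u2, p.cov_u12, p.sigma_e], rtol=1e-10)


class TestFit:
    def test_pinned_variances_match_glm_and_ols(self, reference_truth):
        truth = tpi.FoodGroupTruth("z", reference_truth.beta_prob,
                                   reference_truth.beta_amt, 0.0, 0.0, 0.0, 0.6)
        ds = simulate_one_group(truth, 400, seed=13)
        res = tpi.fit(ds.data, variant="uncorrelated", pin_variances=True)
        md = _ModelData(ds.data)
        logit = sm.GLM(md.consf, md.X, family=sm.families.Binomial()).fit()
        ols = sm.OLS(md.logg[md.cons], md.X[md.cons]).fit()
        np.testing.assert_allclose(res.params.beta_prob, logit.params, atol=1e-4)
        np.testing.assert_allclose(res.params.beta_amt, ols.params, atol=1e-4)

    def test_row_permutation_invariance(self, reference_truth):
        ds = simulate_one_group(reference_truth, 150, seed=14)
        res1 = tpi.fit(ds.data, variant="correlated")
        shuffled = ds.data.sample(frac=1.0, random_state=0)
        res2 = tpi.fit(shuffled, variant="correlated")
        np.testing.assert_allclose(res1.theta, res2.theta, atol=1e-6)

    def test_correlated_loglik_dominates_uncorrelated(self, reference_truth):
        ds = simulate_one_group(reference_truth, 200, seed=15)
        corr = tpi.fit(ds.data, variant="correlated")
        uncorr = tpi.fit(ds.data, variant="uncorrelated")
        assert corr.loglik >= uncorr.loglik - 1e-4
        assert "cov_u12" not in uncorr.natural_names

    def test_exposure_rescaling_equivariance(self, reference_truth):
        ds = simulate_one_group(reference_truth, 200, seed=16)
        res = tpi.fit(ds.data, variant="correlated")
        scaled = ds.data.copy()
        scaled["exposure"] = scaled["exposure"] / 100.0
        res_s = tpi.fit(scaled, variant="correlated")
        np.testing.assert_allclose(res_s.params.beta_prob[1] / 100.0,
                                   res.params.beta_prob[1], rtol=1e-2)
        np.testing.assert_allclose(res_s.params.beta_amt[0],
                                   res.params.beta_amt[0], rtol=1e-3)

    def test_loglik_at_truth_beats_perturbation(self, reference_truth):
        ds = simulate_one_group(reference_truth, 800, seed=17)
        t = reference_truth
        truth_params = TwoPartParams(t.beta_prob, t.beta_amt, t.sigma_u1,
                                     t.sigma_u2, t.cov_u12, t.sigma_e)
        perturbed = TwoPartParams(t.beta_prob + 0.3, t.beta_amt - 0.3,
                                  t.sigma_u1 * 1.5, t.sigma_u2 * 0.6,
                                  0.0, t.sigma_e * 1.4)
        assert (dataset_loglik(truth_params, ds.data)
                > dataset_loglik(perturbed, ds.data))

    def test_separation_raises_actionable_error(self):
        df = pd.DataFrame([
            {"participant_id": i, "day": d, "exposure": 1.0, "sex": 0,
             "grams": 10.0}
            for i in range(5) for d in (1, 2)])
        with pytest.raises(SeparationError, match="amount"):
            tpi.fit(df)
        df["grams"] = 0.0
        with pytest.raises(SeparationError, match="probability"):
            tpi.fit(df)

    def test_single_part_amount_fit_runs(self, reference_truth):
        truth = tpi.FoodGroupTruth("always", [50, 0, 0, 0],
                                   reference_truth.beta_amt, 0.0,
                                   0.6, 0.0, 0.5)
        ds = simulate_one_group(truth, 150, seed=18)
        res = tpi.fit(ds.data, variant="uncorrelated", parts="amount")
        assert res.converged
        assert res.parts == "amount"
        assert np.isnan(res.params.beta_prob).all()

    def test_fit_json_roundtrip(self, reference_fit, tmp_path):
        p = tmp_path / "fit.json"
        reference_fit.to_json(p)
        back = tpi.FitResult.from_json(p)
        np.testing.assert_allclose(back.theta, reference_fit.theta)
        assert back.variant == reference_fit.variant
        np.testing.assert_allclose(back.param_cov, reference_fit.param_cov)


class TestVariantSelection:
    def make(self, grams_fn, n=100):
        return pd.DataFrame([
            {"participant_id": i, "day": d, "exposure": 50.0, "sex": i % 2,
             "grams": grams_fn(i, d)}
            for i in range(n) for d in (1, 2)])

    def test_always_consumed_gets_uncorrelated(self):
        df = self.make(lambda i, d: 10.0)
        variant, reason = tpi.select_variant(df)
        assert variant == "uncorrelated"
        assert "no zero days" in reason

    def test_rarely_consumed_gets_uncorrelated(self):
        # 2% of participants consume, on a single day each
        df = self.make(lambda i, d: 10.0 if (i < 2 and d == 1) else 0.0)
        variant, _ = tpi.select_variant(df)
        assert variant == "uncorrelated"

    def test_well_mixed_group_gets_correlated(self, reference_truth):
        ds = simulate_one_group(reference_truth, 200, seed=19)
        variant, reason = tpi.select_variant(ds.data)
        assert variant == "correlated"
        assert "discordant" in reason
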
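"""Measurement-error models and the Monte Carlo usual-intake distribution."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from dietgap.targets import ScaledTarget
from dietgap.usual_intake import (
    AmountModelParams,
    IdentifiabilityError,
    TwoPartModelParams,
    boxcox,
    boxcox_inv,
    build_design,
    fit_amount_model,
    fit_two_part_model,
    implied_population_moments,
    summarize_and_attain,
    usual_intake_distribution,
    _fit_lmm_at_lambda,
)


def simulate_amount(seed, n=500, d=3, beta0=100.0, sigma_u=20.0, sigma_e=30.0):
    rng = np.random.default_rng(seed)
    person = np.repeat(np.arange(n), d)
    u = sigma_u * rng.standard_normal(n)
    y = np.clip(beta0 + u.repeat(d) + sigma_e * rng.standard_normal(n * d), 0.1, None)
    X = np.ones((n * d, 1))
    return y, person, X, ["intercept"]


class TestAmountModel:
    def test_recovers_simulated_truth_on_measurement_scale(self):
        """With identity-transform truth, the implied population mean,
        between-person SD and within-person SD recover the generating
        (100, 20, 30) within 10% relative."""
        y, person, X, names = simulate_amount(seed=0)
        params = fit_amount_model(y, person, X, names)
        m = implied_population_moments(params)
        assert m["mean"] == pytest.approx(100.0, rel=0.10)
        assert m["sd_between"] == pytest.approx(20.0, rel=0.10)
        assert m["sd_within"] == pytest.approx(30.0, rel=0.10)

    def test_inner_lmm_matches_statsmodels_mixedlm(self):
        """The closed-form profiled ML fit agrees with an independent
        generic mixed-model fit (statsmodels MixedLM) at a fixed transform."""
        import statsmodels.api as sm

        y, person, X, names = simulate_amount(seed=1, n=150)
        z = boxcox(y, 0.5)
        beta, su2, se2, ll = _fit_lmm_at_lambda(z, X, person)
        mu, s = z.mean(), z.std()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM((z - mu) / s, X, groups=person).fit(reml=False)
        assert ll == pytest.approx(float(res.llf) - len(z) * np.log(s), abs=1e-3)
        assert beta[0] == pytest.approx(float(res.fe_params[0]) * s + mu, rel=1e-4)
        assert su2 == pytest.approx(float(np.asarray(res.cov_re)[0, 0]) * s**2, rel=1e-3)
        assert se2 == pytest.approx(float(res.scale) * s**2, rel=1e-3)

    def test_no_within_person_noise(self):
        rng = np.random.default_rng(2)
        n, d = 200, 3
        person = np.repeat(np.arange(n), d)
        y = np.clip(100.0 + 20.0 * rng.standard_normal(n), 1.0, None).repeat(d)
        params = fit_amount_model(y, person, np.ones((n * d, 1)), ["intercept"])
        m = implied_population_moments(params)
        assert m["sd_within"] < 0.05 * m["sd_between"]
        assert m["mean"] == pytest.approx(100.0, rel=0.05)

    def test_zero_days_trigger_shift(self):
        y, person, X, names = simulate_amount(seed=3, n=200)
        y[::7] = 0.0
        params = fit_amount_model(y, person, X, names)
        assert params.shift > 0.0

    def test_rank_deficient_design_rejected(self):
        y, person, X, names = simulate_amount(seed=4, n=50)
        X2 = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_amount_model(y, person, X2, names + ["dup"])

    def test_single_day_persons_not_identifiable(self):
        y, person, X, names = simulate_amount(seed=5, n=100, d=1)
        with pytest.raises(IdentifiabilityError):
            fit_amount_model(y, person, X, names)


def simulate_two_part(seed, n=400, d=4, p_logit=-0.85, rho=0.5, lam=0.4,
                      beta0=8.0, s1=1.0, s2=1.0, se=1.2):
    rng = np.random.default_rng(seed)
    person = np.repeat(np.arange(n), d)
    zz = rng.standard_normal((n, 2))
    u1 = s1 * zz[:, 0]
    u2 = s2 * (rho * zz[:, 0] + np.sqrt(1 - rho**2) * zz[:, 1])
    c = rng.random(n * d) < expit(p_logit + u1.repeat(d))
    eta = beta0 + u2.repeat(d) + se * rng.standard_normal(n * d)
    y = np.where(c, boxcox_inv(eta, lam), 0.0)
    return y, person, np.ones((n * d, 1)), ["intercept"]


class TestTwoPartModel:
    def test_all_positive_degenerates_to_amount_model(self):
        y, person, X, names = simulate_amount(seed=6, n=200)
        tp = fit_two_part_model(y, person, X, names)
        assert tp.prob_degenerate
        one = fit_amount_model(y, person, X, names)
        cov = pd.DataFrame({"intercept": np.ones(100)})
        d_tp = usual_intake_distribution(tp, cov, n_mc=20_000, seed=9)
        d_one = usual_intake_distribution(one, cov, n_mc=20_000, seed=9)
        assert d_tp.mean == pytest.approx(d_one.mean, rel=0.01)
        np.testing.assert_array_equal(d_tp.values, d_one.values)

    def test_all_zero_person_is_tolerated(self):
        y, person, X, names = simulate_two_part(seed=7, n=150)
        y[person == 0] = 0.0
        tp = fit_two_part_model(y, person, X, names)
        assert np.isfinite(tp.loglik)

    def test_no_positive_days_raises(self):
        n, d = 50, 3
        person = np.repeat(np.arange(n), d)
        with pytest.raises(ValueError, match="positive"):
            fit_two_part_model(np.zeros(n * d), person, np.ones((n * d, 1)), ["intercept"])

    def test_rho_recovery(self):
        """Correlation between consumption propensity and amount is
        recovered from episodic data (median error over seeds)."""
        errs = []
        for seed in range(5):
            y, person, X, names = simulate_two_part(seed=100 + seed, rho=0.5)
            tp = fit_two_part_model(y, person, X, names)
            errs.append(abs(tp.rho - 0.5))
        assert float(np.median(errs)) <= 0.15


def amount_params(lam=1.0, beta0=99.0, names=("intercept",), su=20.0, se=30.0):
    return AmountModelParams(
        lam=lam, beta=np.array([beta0]), beta_names=tuple(names),
        sigma_u2=su**2, sigma_e2=se**2, loglik=0.0,
    )


class TestDistribution:
    cov = pd.DataFrame({"intercept": np.ones(25)})

    def test_identity_transform_matches_normal(self):
        """lam=1, no covariates: within-person noise averages out and the
        usual-intake distribution is Normal(mean, sigma_u^2)."""
        d = usual_intake_distribution(amount_params(), self.cov, n_mc=50_000, seed=11)
        se_mean = 20.0 / np.sqrt(50_000)
        assert d.mean == pytest.approx(100.0, abs=3 * se_mean + 0.05)
        assert d.percentile(50) == pytest.approx(100.0, abs=0.4)

    def test_same_seed_bit_identical(self):
        d1 = usual_intake_distribution(amount_params(), self.cov, n_mc=5000, seed=13)
        d2 = usual_intake_distribution(amount_params(), self.cov, n_mc=5000, seed=13)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_weekend_weighting(self):
        """A weekend effect enters with weight 2/7."""
        p = AmountModelParams(
            lam=1.0, beta=np.array([99.0, 7.0]), beta_names=("intercept", "weekend"),
            sigma_u2=0.0, sigma_e2=1.0, loglik=0.0,
        )
        d = usual_intake_distribution(p, self.cov, n_mc=1000, seed=17)
        assert d.values[0] == pytest.approx(100.0 + 7.0 * 2.0 / 7.0, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            usual_intake_distribution(amount_params(), self.cov, n_mc=0, seed=1)
        with pytest.raises(ValueError):
            usual_intake_distribution(amount_params(), self.cov, n_mc=10, seed=None)

    def test_two_part_probability_scales_intake(self):
        amt = amount_params(su=0.0, se=0.0)
        tp = TwoPartModelParams(
            amount=amt, beta_p=np.array([0.0]), beta_p_names=("intercept",),
            sigma_u1_2=0.0, rho=0.0, loglik=0.0,
        )
        d = usual_intake_distribution(tp, self.cov, n_mc=100, seed=19)
        assert d.values[0] == pytest.approx(50.0)  # p = 0.5 everywhere


class TestSummaries:
    def test_percentiles_monotone_and_attainment(self):
        rng = np.random.default_rng(23)
        from dietgap.usual_intake import UsualIntakeDistribution

        d = UsualIntakeDistribution(np.abs(rng.standard_normal(10_000)) * 50)
        t = ScaledTarget("vegetables", 60.0, 40.0, 120.0, "minimum")
        s = summarize_and_attain(d, t)
        assert s["p25"] <= s["p50"] <= s["p75"]
        assert s["pct_below"] + s["pct_within"] + s["pct_above"] == 100.0
        expected = 100.0 * np.mean(d.values >= 60.0)
        assert s["pct_meeting"] == pytest.approx(expected)

    def test_normal_tail_closed_form(self):
        d = usual_intake_distribution(
            amount_params(), pd.DataFrame({"intercept": [1.0]}), n_mc=100_000, seed=29
        )
        t = ScaledTarget("whole_grains", 122.0, None, None, "minimum")
        s = summarize_and_attain(d, t)
        expected = 100.0 * norm.sf((122.0 - 100.0) / 20.0)
        se = 100.0 * np.sqrt(expected / 100 * (1 - expected / 100) / 100_000)
        assert s["pct_meeting"] == pytest.approx(expected, abs=3 * se + 0.1)

    def test_boundary_point_mass(self):
        from dietgap.usual_intake import UsualIntakeDistribution

        d = UsualIntakeDistribution(np.full(1000, 42.0))
        t = ScaledTarget("eggs", 42.0, 0.0, 80.0, "maximum")
        s = summarize_and_attain(d, t)
        assert s["pct_meeting"] == 100.0
        assert s["pct_within"] == 100.0

    def test_zero_minimum_target_always_met(self):
        from dietgap.usual_intake import UsualIntakeDistribution

        d = UsualIntakeDistribution(np.linspace(0, 10, 100))
        t = ScaledTarget("fish", 0.0, None, None, "minimum")
        assert summarize_and_attain(d, t)["pct_meeting"] == 100.0


def test_build_design_age_dummies():
    df = pd.DataFrame(
        {
            "age_years": [3.2, 4.7, 4.1, 3.9],
            "sex": ["girl", "boy", "boy", "girl"],
            "weekend": [0.0, 1.0, 0.0, 1.0],
        }
    )
    X, names = build_design(df)
    assert names == ["intercept", "age4", "boy", "weekend"]
    np.testing.assert_array_equal(X[:, 1], [0, 1, 1, 0])
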
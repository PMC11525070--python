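"""Linear predictor, annualized likelihood, MCMC correctness and curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

import beechsurv as bs
from beechsurv.model import (
    BayesianTreeSurvival,
    ModelCoefficients,
    ModelSpec,
    annual_survival,
    interval_survival,
    linear_predictor,
    log_likelihood,
    predict_survival_curve,
)
from beechsurv.validation import (
    grid_posterior,
    intercept_only_observations,
    intercept_grid_check,
)


def obs_row(**overrides):
    base = {
        "tree_id": "t1",
        "plot_id": "P1",
        "start_year": 1983,
        "end_year": 1987,
        "delta_t_years": 4.0,
        "period_index": 1,
        "outcome": 1,
        "diameter_std": 0.0,
        "diameter_sq_std": 0.0,
        "local_ba_std": 0.0,
        "growth_prev": 0.0,
        "growth_lag": 0.0,
        "soil_p_std": 0.0,
        "landform_std": 0.0,
        "elevation_std": 0.0,
        "distance_std": 0.0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestModelSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            ModelSpec(include_prev_growth=False, include_prev_growth_x_elev=True)
        with pytest.raises(ValueError):
            ModelSpec(include_lag_growth=False, include_lag_growth_x_elev=True)

    def test_named_specs(self):
        assert "lag_x_ele" not in ModelSpec.selected().active_columns()
        assert "lag_x_ele" in ModelSpec.full().active_columns()
        base_cols = ModelSpec.base().active_columns()
        assert "growth_prev" not in base_cols and "growth_lag" not in base_cols
        assert {"diameter", "basal_area", "elevation", "distance"} <= set(base_cols)


class TestLinearPredictor:
    def test_intercept_only_value(self):
        coef = ModelCoefficients(values={"mu": np.array([3.691, 0.0, 0.0])})
        eta = linear_predictor(obs_row(), coef)
        assert eta[0] == pytest.approx(3.691)

    def test_all_zero_coefficients(self):
        coef = ModelCoefficients()
        eta = linear_predictor(obs_row(growth_prev=5.0, diameter_std=100.0), coef)
        assert eta[0] == 0.0

    def test_previous_growth_contribution(self):
        coef = ModelCoefficients(
            values={"mu": np.array([3.691, 0, 0]), "gamma_g": np.array([0.575, 0, 0])}
        )
        eta = linear_predictor(obs_row(growth_prev=1.0), coef)
        assert eta[0] == pytest.approx(4.266)

    def test_plot_effect_added(self):
        coef = ModelCoefficients(
            values={"mu": np.array([1.0, 0, 0])}, sigma_s=1.0,
            plot_effects={"P1": 0.5},
        )
        assert linear_predictor(obs_row(), coef)[0] == pytest.approx(1.5)

    def test_bad_period_rejected(self):
        coef = ModelCoefficients()
        with pytest.raises(ValueError):
            linear_predictor(obs_row(period_index=4), coef)


class TestSurvivalTransforms:
    def test_inverse_logit_values(self):
        assert annual_survival(0.0) == pytest.approx(0.5)
        assert annual_survival(3.691) == pytest.approx(0.9756, abs=2e-4)

    def test_monotone(self):
        assert annual_survival(2.0) > annual_survival(1.0)

    def test_interval_identity_and_oracle(self):
        assert interval_survival(0.9, 1.0) == pytest.approx(0.9)
        # 0.9756**6 = 0.86224...; agrees with the rounded printed 0.8625
        assert interval_survival(0.9756, 6) == pytest.approx(0.9756**6, rel=1e-12)
        assert interval_survival(0.9756, 6) == pytest.approx(0.8625, abs=5e-4)

    @given(
        st.floats(min_value=0.01, max_value=0.999),
        st.floats(min_value=1.0, max_value=10.0),
    )
    def test_interval_survival_below_annual(self, s, dt):
        assert interval_survival(s, dt) <= s + 1e-12


class TestLogLikelihood:
    def test_certain_survival_term_is_zero(self):
        coef = ModelCoefficients(values={"mu": np.array([500.0, 0, 0])})
        total, pointwise = log_likelihood(obs_row(), coef)
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_death_term_oracle(self):
        # annual survival 0.9756 over 6 years, tree died
        coef = ModelCoefficients(values={"mu": np.array([3.691, 0, 0])})
        total, _ = log_likelihood(
            obs_row(outcome=0, delta_t_years=6.0, end_year=1989), coef
        )
        s = expit(3.691)
        assert total == pytest.approx(np.log(1 - s**6), rel=1e-9)
        assert total == pytest.approx(-1.984, abs=2e-3)

    def test_unit_interval_reduces_to_bernoulli(self):
        coef = ModelCoefficients(values={"mu": np.array([1.3, 0, 0])})
        s = expit(1.3)
        t_alive, _ = log_likelihood(obs_row(delta_t_years=1.0), coef)
        t_dead, _ = log_likelihood(obs_row(delta_t_years=1.0, outcome=0), coef)
        assert t_alive == pytest.approx(np.log(s))
        assert t_dead == pytest.approx(np.log(1 - s))

    def test_deviance_nonnegative(self, small_obs):
        coef = ModelCoefficients(values={"mu": np.array([3.0, 3.0, 3.0])})
        total, pointwise = log_likelihood(small_obs, coef)
        assert -2.0 * total >= 0.0
        assert (pointwise <= 1e-12).all()


class TestMCMC:
    def test_intercept_posterior_matches_grid_oracle(self):
        res = intercept_grid_check(seed=42, n=200)
        assert res["mean_abs_diff"] < 0.05
        assert res["sd_rel_diff"] < 0.10

    def test_grid_oracle_is_consistent_with_itself(self):
        obs = intercept_only_observations(seed=1, n=50)
        m1, s1 = grid_posterior(obs)
        m2, s2 = grid_posterior(obs, grid=np.linspace(-2, 8, 2001))
        assert m1 == pytest.approx(m2, abs=1e-3)
        assert s1 == pytest.approx(s2, rel=1e-2)

    def test_fixed_seed_reproduces_draws(self, small_obs):
        kw = dict(seed=5, chains=2, iterations=300, burn_in=100, thin=3)
        a = BayesianTreeSurvival(**kw).fit(small_obs)
        b = BayesianTreeSurvival(**kw).fit(small_obs)
        pd.testing.assert_frame_equal(a.draws_, b.draws_)
        assert np.array_equal(a.pointwise_loglik_, b.pointwise_loglik_)

    def test_retained_draw_count(self, small_fit, small_obs):
        # retained = chains x iterations / thin
        assert small_fit.fit_.n_draws == 3 * 900 // 3
        assert small_fit.pointwise_loglik_.shape == (900, len(small_obs))

    def test_sklearn_estimator_contract(self, small_obs):
        from sklearn.base import clone

        est = BayesianTreeSurvival(seed=1)
        params = est.get_params()
        assert params["spec"] == "selected" and params["chains"] == 3
        clone(est)
        est2 = BayesianTreeSurvival(seed=1, chains=2, iterations=120, burn_in=60, thin=3)
        est2.fit(small_obs.head(300))
        s = est2.predict_annual_survival(small_obs.head(5))
        assert ((s > 0) & (s < 1)).all()

    def test_interval_credible_calibration_for_intercept(self):
        """Across 20 small simulated forests, the 95% interval for the
        pre-earthquake intercept covers the truth at nominal rate."""
        hits = 0
        for seed in range(20):
            ds = bs.simulate_forest(
                bs.SimulationConfig(
                    seed=1000 + seed, n_plots=24, n_transects=8,
                    stems_per_subplot=2.5,
                )
            )
            obs, _ = bs.assemble_observations(ds.trees, ds.plots)
            est = BayesianTreeSurvival(
                seed=seed, chains=3, iterations=1200, burn_in=400, thin=4
            )
            est.fit(obs)
            lo, hi = est.fit_.credible_interval("mu[1]")
            hits += lo <= 3.691 <= hi
        assert 16 <= hits <= 20


class TestSurvivalCurves:
    def test_degenerate_posterior_has_zero_band(self, degenerate_fit_factory):
        fit = degenerate_fit_factory(
            {"mu[1]": 3.0, "gamma_g[1]": 0.5, "gamma_g_x_ele[1]": 0.0,
             "gamma_ele[1]": 0.2}
        )
        curve = predict_survival_curve(fit, 1, 1000.0, np.linspace(0, 2, 5))
        assert np.allclose(curve["survival_lo"], curve["survival_hi"])
        assert np.allclose(curve["survival_lo"], curve["survival_mean"])

    def test_monotone_when_slope_positive(self, degenerate_fit_factory):
        fit = degenerate_fit_factory(
            {"mu[1]": 3.0, "gamma_g[1]": 0.6, "gamma_g_x_ele[1]": -0.1,
             "gamma_ele[1]": 0.2}
        )
        for elev in (800.0, 1000.0, 1200.0):
            ele_std = (elev - 1000) / 100
            slope = 0.6 - 0.1 * ele_std
            curve = predict_survival_curve(fit, 1, elev, np.linspace(-1, 3, 30))
            diffs = np.diff(curve["survival_mean"].to_numpy())
            if slope > 0:
                assert (diffs >= -1e-12).all()

    def test_grid_trimmed_to_central_95(self, small_obs, small_fit):
        g = small_obs[small_obs.period_index == 1]["growth_prev"]
        wide = np.linspace(g.min() - 5, g.max() + 5, 60)
        with pytest.warns(UserWarning, match="trimmed"):
            curve = predict_survival_curve(
                small_fit.fit_, 1, 1000.0, wide, observations=small_obs
            )
        assert curve["growth_prev"].min() >= np.quantile(g, 0.0)
        assert len(curve) < len(wide)

    def test_unknown_period_rejected(self, small_fit):
        with pytest.raises(ValueError):
            predict_survival_curve(small_fit.fit_, 7, 1000.0, [0.5])
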
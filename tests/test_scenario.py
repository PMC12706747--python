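"""Scenario model: fitting, what-if projections, bounded optimization."""

from dataclasses import replace

import numpy as np
import pytest

from uhctraj.data import CoverageValidationError, IndicatorPanel, inverse_logit
from uhctraj.scenario import (
    DegenerateDesignError,
    FACTORS,
    ScenarioLogisticModel,
    ScenarioSpec,
    fit_scenario_model,
    project_scenario,
    required_increase,
    scenario_deltas,
)
from uhctraj.synthetic import PanelConfig, generate_panel

from conftest import make_known_fit


class TestFit:
    def test_noiseless_recovery(self, noiseless_panel):
        cfg = replace(PanelConfig(), noise_sd=0.0, seed=3)
        raw = fit_scenario_model(noiseless_panel).raw_coefficients
        for key, truth in [
            ("alpha0", cfg.true_alpha0),
            ("beta_year", cfg.true_beta_year),
            ("beta_c", cfg.true_beta_c),
            ("beta_e", cfg.true_beta_e),
            ("beta_h", cfg.true_beta_h),
        ]:
            assert abs(raw[key] - truth) < 1e-4, key

    def test_constant_covariate_rejected_naming_column(self, flat_covariate_panel):
        with pytest.raises(DegenerateDesignError, match="'c'"):
            fit_scenario_model(flat_covariate_panel)

    def test_too_few_years_rejected(self):
        p = IndicatorPanel(
            [2017, 2018, 2019, 2020, 2021],
            [0.3, 0.32, 0.34, 0.36, 0.38],
            [0.1, 0.12, 0.13, 0.15, 0.16],
            [10, 11, 12, 13, 14],
            [1.0, 1.1, 1.2, 1.3, 1.4],
        )
        with pytest.raises(CoverageValidationError, match="6 years"):
            fit_scenario_model(p)

    def test_currency_rescaling_leaves_projections_unchanged(self, noisy_panel):
        rescaled = IndicatorPanel(
            noisy_panel.years,
            noisy_panel.coverage,
            noisy_panel.c,
            noisy_panel.e * 1000.0,
            noisy_panel.h,
        )
        f1 = fit_scenario_model(noisy_panel)
        f2 = fit_scenario_model(rescaled)
        spec = lambda panel: ScenarioSpec({"e": 2.0}, 2030, int(panel.years[-1]))
        assert project_scenario(f1, noisy_panel, spec(noisy_panel)) == pytest.approx(
            project_scenario(f2, rescaled, spec(rescaled)), rel=1e-9
        )

    @pytest.mark.filterwarnings("ignore:Perfect separation")
    def test_fractional_logit_close_to_ols_on_smooth_panel(self, noiseless_panel):
        ols = fit_scenario_model(noiseless_panel, method="ols")
        frac = fit_scenario_model(noiseless_panel, method="fractional")
        assert frac.beta_year == pytest.approx(ols.beta_year, rel=0.05)


class TestProjectScenario:
    def test_identity_scenario_reproduces_baseline(self, noisy_panel):
        fit = fit_scenario_model(noisy_panel)
        ref = int(noisy_panel.years[-1])
        base = project_scenario(fit, noisy_panel, ScenarioSpec({}, 2030, ref))
        ones = project_scenario(
            fit, noisy_panel, ScenarioSpec({f: 1.0 for f in FACTORS}, 2030, ref)
        )
        assert ones == base

    def test_doubling_shifts_logit_by_known_amount(self, flat_covariate_panel):
        # Unit-standardization fixture: doubling e adds beta_e * e_base to
        # the horizon logit exactly.
        fit = make_known_fit()
        ref = int(flat_covariate_panel.years[-1])
        base = project_scenario(fit, flat_covariate_panel, ScenarioSpec({}, 2030, ref))
        doubled = project_scenario(
            fit, flat_covariate_panel, ScenarioSpec({"e": 2.0}, 2030, ref)
        )
        e_base = 1.0  # constant covariate path extrapolates to its level
        z_base = np.log(base / (1 - base))
        z_doubled = np.log(doubled / (1 - doubled))
        assert z_doubled - z_base == pytest.approx(fit.beta_e * e_base, abs=1e-10)

    def test_doubling_positive_coefficient_never_decreases(self, noiseless_panel):
        fit = fit_scenario_model(noiseless_panel)
        ref = int(noiseless_panel.years[-1])
        assert fit.beta_h > 0
        base = project_scenario(fit, noiseless_panel, ScenarioSpec({}, 2030, ref))
        up = project_scenario(fit, noiseless_panel, ScenarioSpec({"h": 2.0}, 2030, ref))
        assert up >= base

    def test_horizon_before_last_observation_rejected(self, noisy_panel):
        fit = fit_scenario_model(noisy_panel)
        with pytest.raises(CoverageValidationError):
            project_scenario(fit, noisy_panel, ScenarioSpec({}, 2010, 2010))


class TestScenarioDeltas:
    def test_null_effects_give_zero_deltas(self, flat_covariate_panel):
        fit = make_known_fit(beta_c=0.0, beta_e=0.0, beta_h=0.0)
        df = scenario_deltas(fit, flat_covariate_panel, 2030)
        assert np.allclose(df["delta_pp"], 0.0, atol=1e-12)

    def test_table_matches_direct_projection_calls(self, noisy_panel):
        fit = fit_scenario_model(noisy_panel)
        df = scenario_deltas(fit, noisy_panel, 2030)
        ref = int(noisy_panel.years[-1])
        for _, row in df.iterrows():
            mult = (
                {}
                if row["scenario"] == "baseline"
                else {f: 2.0 for f in FACTORS}
                if row["scenario"] == "combined"
                else {row["scenario"]: 2.0}
            )
            direct = project_scenario(fit, noisy_panel, ScenarioSpec(mult, 2030, ref))
            assert row["coverage_pct"] == pytest.approx(100 * direct, abs=1e-9)

    def test_combined_delta_below_sum_in_concave_regime(self, flat_covariate_panel):
        # Baseline above 0.5: the logistic is concave, so simultaneous
        # increases yield less than the sum of individual gains.
        fit = make_known_fit(alpha0=0.5, beta_c=0.3, beta_e=0.3, beta_h=0.3)
        df = scenario_deltas(fit, flat_covariate_panel, 2030).set_index("scenario")
        singles = df.loc[list(FACTORS), "delta_pp"].sum()
        assert df.loc["combined", "delta_pp"] <= singles + 1e-9


def grid_objective(fit, panel, target, horizon, grids):
    """Exhaustive-search oracle over per-factor percent-increase grids."""
    ref = int(panel.years[-1])
    from uhctraj.scenario import extrapolate_covariate

    base = {
        f: extrapolate_covariate(panel.years, getattr(panel, f), horizon)
        for f in FACTORS
    }
    gc, ge, gh = np.meshgrid(*grids, indexing="ij", sparse=True)
    t = horizon - fit.reference_year
    z = (
        fit.alpha0
        + fit.beta_year * t
        + fit.beta_c * (base["c"] * (1 + gc / 100) - fit.standardization["c"][0]) / fit.standardization["c"][1]
        + fit.beta_e * (base["e"] * (1 + ge / 100) - fit.standardization["e"][0]) / fit.standardization["e"][1]
        + fit.beta_h * (base["h"] * (1 + gh / 100) - fit.standardization["h"][0]) / fit.standardization["h"][1]
    )
    obj = (inverse_logit(z) - target) ** 2
    idx = np.unravel_index(np.argmin(obj), obj.shape)
    best = [float(g[i]) for g, i in zip(grids, idx)]
    return float(obj[idx]), best


class TestRequiredIncrease:
    def test_target_already_met_returns_zero_increases(self, flat_covariate_panel):
        fit = make_known_fit(alpha0=2.0)  # baseline well above 80%
        res = required_increase(fit, flat_covariate_panel, target=0.8, horizon_year=2030)
        assert res.increase_pct == {f: 0.0 for f in FACTORS}
        assert res.objective_value == 0.0
        assert res.converged

    def test_single_factor_matches_fine_grid_argmin(self, flat_covariate_panel):
        # Only e has an effect; the grid argmin along e is unique.
        fit = make_known_fit(beta_c=0.0, beta_e=1.2, beta_h=0.0, alpha0=-0.5)
        res = required_increase(fit, flat_covariate_panel, target=0.8, horizon_year=2030)
        grid = np.arange(0.0, 100.05, 0.1)
        _, best = grid_objective(
            fit, flat_covariate_panel, 0.8, 2030,
            [np.array([0.0]), grid, np.array([0.0])],
        )
        assert res.objective_value < 1e-8
        assert abs(res.increase_pct["e"] - best[1]) <= 0.1 + 1e-9

    def test_three_factor_objective_matches_grid_oracle(self, flat_covariate_panel):
        fit = make_known_fit(beta_c=0.4, beta_e=0.8, beta_h=0.5, alpha0=-0.4)
        res = required_increase(fit, flat_covariate_panel, target=0.8, horizon_year=2030)
        grid = np.arange(0.0, 100.5, 0.5)
        obj_grid, _ = grid_objective(
            fit, flat_covariate_panel, 0.8, 2030, [grid, grid, grid]
        )
        assert res.objective_value <= obj_grid + 1e-8
        assert res.objective_value < 1e-8
        assert res.converged

    def test_infeasible_target_pins_factors_at_bound(self, flat_covariate_panel):
        # Non-positive coefficients: increases push coverage away from an
        # unattainable target, so the optimum sits at the lower bound.
        fit = make_known_fit(beta_c=-0.3, beta_e=-0.5, beta_h=-0.2, alpha0=-1.0)
        res = required_increase(fit, flat_covariate_panel, target=0.9, horizon_year=2030)
        assert res.objective_value > 0.0
        assert all(res.at_bound.values())
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in res.increase_pct.values())

    def test_invalid_target_rejected(self, flat_covariate_panel):
        fit = make_known_fit()
        with pytest.raises(CoverageValidationError):
            required_increase(fit, flat_covariate_panel, target=1.2)


class TestNoisyRecovery:
    def test_median_coefficient_error_under_ten_percent(self):
        cfg = PanelConfig()
        truth = {
            "beta_year": cfg.true_beta_year,
            "beta_c": cfg.true_beta_c,
            "beta_e": cfg.true_beta_e,
            "beta_h": cfg.true_beta_h,
        }
        errs = {k: [] for k in truth}
        for seed in range(30):  # the full 100-replicate check runs in acceptance
            raw = fit_scenario_model(
                generate_panel(replace(cfg, seed=seed))
            ).raw_coefficients
            for k in errs:
                errs[k].append(abs(raw[k] - truth[k]) / abs(truth[k]))
        for k, v in errs.items():
            assert np.median(v) < 0.10, k


class TestEstimatorInterface:
    def test_sklearn_fit_predict(self, noisy_panel):
        X = np.column_stack(
            [noisy_panel.years, noisy_panel.c, noisy_panel.e, noisy_panel.h]
        )
        m = ScenarioLogisticModel().fit(X, noisy_panel.coverage)
        pred = m.predict(X)
        assert pred.shape == noisy_panel.coverage.shape
        # In-sample fit should track observed coverage closely.
        assert np.corrcoef(pred, noisy_panel.coverage)[0, 1] > 0.98

    def test_clone_and_params(self):
        from sklearn.base import clone

        m = ScenarioLogisticModel(reference_year=2000)
        assert clone(m).get_params() == {"reference_year": 2000, "method": "ols"}
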
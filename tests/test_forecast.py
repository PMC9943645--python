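"""Scenario resampling, projections, ablations and forecast skill."""

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import norm

import stagecast as sc
from stagecast.demography import A
from stagecast.forecast import _historical_inter
from stagecast.synth import DEFAULT_STD

from test_inference import degenerate_posterior


@pytest.fixture(scope="module")
def observed_rain():
    return sc.make_rainfall(15, mean=500, sd=150, seed=3)


class TestSampleRainfall:
    def test_p_below_one_draws_only_below_mean(self, observed_rain):
        spec = sc.ScenarioSpec(kind="climate_change", p_below=1.0)
        rng = np.random.default_rng(0)
        seq = sc.sample_rainfall(observed_rain, spec, 500, rng)
        assert np.all(seq < observed_rain.mean)

    def test_below_mean_fraction_matches_p(self, observed_rain):
        spec = sc.ScenarioSpec(kind="climate_change", p_below=0.8)
        rng = np.random.default_rng(1)
        seq = sc.sample_rainfall(observed_rain, spec, 10000, rng)
        frac = np.mean(seq < observed_rain.mean)
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(frac - 0.8) < 3 * se

    def test_baseline_support_is_observed_values(self, observed_rain):
        spec = sc.ScenarioSpec(kind="baseline")
        seq = sc.sample_rainfall(observed_rain, spec, 200, np.random.default_rng(2))
        assert set(seq).issubset(set(observed_rain.values))

    def test_degenerate_series_rejected(self):
        flat = sc.RainfallSeries(years=np.arange(3), values=[500.0] * 3)
        with pytest.raises(ValueError, match="constant"):
            sc.sample_rainfall(flat, sc.ScenarioSpec(kind="baseline"), 5,
                               np.random.default_rng(0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sc.ScenarioSpec(kind="asteroid")


def _solo(rain_slope_phi=0.0):
    return sc.SpeciesParams(
        name="solo",
        theta_coefs=[logit(0.75), 0.0, -1.0, 0.0],
        phi_coefs=[logit(0.92), rain_slope_phi, -1.0, 0.0],
        tau=0.25, gamma=0.3, rho=2.0,
    )


class TestRunScenario:
    def test_zero_horizon_returns_initial_abundances(self, observed_rain):
        spec = sc.ScenarioSpec(kind="baseline", horizon=0, n_runs=3)
        init = np.full((1, 2, 3), 7.0)
        res = sc.run_scenario([_solo()], init, spec, np.eye(2), DEFAULT_STD,
                              observed_rain, seed=0)
        np.testing.assert_allclose(res.mean_stages, init)

    def test_severed_interspecific_coupling_identical_runs(self, observed_rain):
        """With all interspecific slopes zero, dynamic and no-dynamic
        projections at equal seeds are identical trajectories."""
        params = [_solo(), _solo().with_(name="other")]
        init = np.full((2, 3, 3), 8.0)
        hist = np.abs(np.random.default_rng(0).normal(10, 4, (2, 3, 5)))
        common = dict(D=np.eye(3), std=DEFAULT_STD, rain_series=observed_rain, seed=9)
        dyn = sc.run_scenario(params, init,
                              sc.ScenarioSpec(kind="baseline", horizon=10, n_runs=5),
                              **common)
        nodyn = sc.run_scenario(params, init,
                                sc.ScenarioSpec(kind="baseline", horizon=10, n_runs=5,
                                                dynamic_interspecific=False),
                                inter_hist=hist, **common)
        np.testing.assert_array_equal(dyn.mean_stages, nodyn.mean_stages)

    def test_climate_scenario_lowers_rain_dependent_species(self, observed_rain):
        """Positive rain slope on adult survival only: the dry scenario
        yields lower mean adult abundance than baseline."""
        params = [_solo(rain_slope_phi=0.8)]
        init = np.full((1, 4, 3), 10.0)
        common = dict(D=np.eye(4), std=DEFAULT_STD, rain_series=observed_rain, seed=5)
        base = sc.run_scenario(params, init,
                               sc.ScenarioSpec(kind="baseline", horizon=30, n_runs=40),
                               **common)
        clim = sc.run_scenario(params, init,
                               sc.ScenarioSpec(kind="climate_change", p_below=0.8,
                                               horizon=30, n_runs=40),
                               **common)
        assert clim.mean_adults.mean() < base.mean_adults.mean()

    def test_no_dynamic_requires_history(self, observed_rain):
        with pytest.raises(ValueError, match="historical"):
            sc.run_scenario([_solo()], np.full((1, 2, 3), 5.0),
                            sc.ScenarioSpec(kind="baseline", dynamic_interspecific=False),
                            np.eye(2), DEFAULT_STD, observed_rain)


class TestCompareScenarios:
    def _result(self, vals):
        spec = sc.ScenarioSpec(kind="baseline", horizon=1, n_runs=1)
        arr = np.asarray(vals, dtype=float)
        stages = np.repeat(arr[:, :, None], 3, axis=2)
        return sc.ScenarioResult(species=["a", "b"], plots=[0, 1], spec=spec,
                                 mean_adults=arr, mean_stages=stages)

    def test_identical_inputs_give_zero_differences(self):
        r = self._result([[3.0, 4.0], [5.0, 6.0]])
        diff = sc.compare_scenarios(r, r)
        assert (diff["delta_adults"] == 0).all()

    def test_constant_offset_recovered(self):
        a = self._result([[3.0, 4.0], [5.0, 6.0]])
        b = self._result([[2.0, 3.0], [4.0, 5.0]])
        diff = sc.compare_scenarios(a, b)
        assert (diff["delta_adults"] == 1.0).all()

    def test_mismatched_designs_rejected(self):
        a = self._result([[3.0, 4.0], [5.0, 6.0]])
        b = self._result([[3.0, 4.0], [5.0, 6.0]])
        b.species = ["a", "z"]
        with pytest.raises(ValueError):
            sc.compare_scenarios(a, b)


class TestEvaluateForecast:
    def test_perfect_prediction(self):
        obs = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        m = sc.evaluate_forecast(obs, obs)
        assert m["mse"] == 0.0
        assert m["r"] == 1.0
        assert (m["r_low"], m["r_high"]) == (1.0, 1.0)

    def test_constant_offset(self):
        obs = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        m = sc.evaluate_forecast(obs + 2.0, obs)
        assert m["mse"] == pytest.approx(4.0)
        assert m["r"] == pytest.approx(1.0)

    def test_hand_computed_five_point_example(self):
        """Frozen arithmetic oracle: MSE, Pearson r and the Fisher-z CI
        computed by hand for a printed 5-point example."""
        pred = np.array([2.0, 5.0, 3.0, 8.0, 6.0])
        obs = np.array([1.0, 6.0, 2.0, 7.0, 7.0])
        m = sc.evaluate_forecast(pred, obs)
        mse = np.mean((pred - obs) ** 2)
        r = np.corrcoef(pred, obs)[0, 1]
        z = np.arctanh(r)
        half = norm.ppf(0.975) / np.sqrt(5 - 3)
        assert m["mse"] == pytest.approx(mse, abs=1e-12)
        assert m["r"] == pytest.approx(r, abs=1e-12)
        assert m["r_low"] == pytest.approx(np.tanh(z - half), abs=1e-12)
        assert m["r_high"] == pytest.approx(np.tanh(z + half), abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sc.evaluate_forecast([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_reports_missing_r(self):
        m = sc.evaluate_forecast([2.0, 2.0, 2.0], [1.0, 5.0, 3.0])
        assert np.isnan(m["r"]) and np.isnan(m["r_low"])
        assert m["mse"] > 0


@pytest.fixture(scope="module")
def setup():
    truth = sc.make_truth(3, effect_scale=0.3, seed=2)
    rain = sc.make_rainfall(12, seed=4)
    topo = sc.grid_topology(6)
    data, _ = sc.simulate_community(truth, topo, 12, rain, seed=6)
    post = degenerate_posterior(truth, rho=[sp.rho for sp in truth],
                                n_draws=60, jitter=0.01, seed=1)
    return data, post


class TestForecastHoldout:

    def test_zero_step_forecast_is_identity(self, setup):
        data, post = setup
        last = int(data.years[-1])
        rep = sc.forecast_holdout(data, post, last, last, seed=0)
        np.testing.assert_allclose(rep.frame["pred_mean"], rep.frame["observed"])
        assert rep.metrics["A"]["mse"] == 0.0
        assert rep.metrics["A"]["r"] == 1.0

    def test_credible_interval_coverage_under_self_simulation(self, setup):
        """Observed cells fall inside the 95% projection interval for the
        vast majority of plot/species/stage cells when the data were
        generated by the same process."""
        data, post = setup
        rep = sc.forecast_holdout(data, post, int(data.years[0]), int(data.years[-1]),
                                  seed=1)
        frame = rep.frame[rep.frame["observed"].notna()]
        covered = ((frame["observed"] >= frame["lo"]) &
                   (frame["observed"] <= frame["hi"])).mean()
        assert covered >= 0.85
        assert rep.n_draws == 120

    def test_report_bounds_ordered_and_metrics_present(self, setup):
        data, post = setup
        rep = sc.forecast_holdout(data, post, int(data.years[0]), int(data.years[-1]),
                                  seed=2, n_draws=40)
        assert (rep.frame["lo"] <= rep.frame["hi"]).all()
        assert {"S", "A"} <= set(rep.metrics)
        assert rep.metrics["A"]["n"] == data.n_plots * data.n_species
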
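import itertools
import time

import numpy as np
import pytest

from tpforc.calibration import (
    NONOCCURRENCE_PENALTY_DAYS,
    ParameterBounds,
    SAConfig,
    fit_model,
    objective_rmse,
    select_optimum_tpforc,
    simulated_annealing,
)
from tpforc.models import ModelFamily, SeriesPredictor, Trigger, make_parameters
from tpforc.synthetic import default_truth, generate_phenology


class TestSimulatedAnnealing:
    CFG = SAConfig(iterations_per_stage=50, n_stages=20, n_restarts=2, rng_seed=1)

    def test_convex_quadratic_found(self):
        x, f, _ = simulated_annealing(lambda v: float((v[0] - 2.3) ** 2), [0.0], [10.0], self.CFG)
        assert abs(x[0] - 2.3) < 1e-2

    def test_same_seed_bit_identical(self):
        run = lambda: simulated_annealing(
            lambda v: float(np.sum((v - 1.0) ** 2)), [-5, -5], [5, 5], self.CFG
        )
        x1, f1, t1 = run()
        x2, f2, t2 = run()
        assert np.array_equal(x1, x2) and f1 == f2 and t1 == t2

    def test_stays_within_bounds(self):
        seen = []
        def obj(v):
            seen.append(v.copy())
            return float(np.sum(v**2))
        lo, hi = np.array([-1.0, 2.0]), np.array([1.0, 3.0])
        simulated_annealing(obj, lo, hi, self.CFG)
        arr = np.array(seen)
        assert np.all(arr >= lo - 1e-12) and np.all(arr <= hi + 1e-12)

    def test_best_trace_non_increasing_across_restarts(self):
        _, _, trace = simulated_annealing(
            lambda v: float(np.cos(v[0] * 3) + 0.1 * v[0] ** 2), [-8.0], [8.0],
            SAConfig(iterations_per_stage=30, n_stages=10, n_restarts=4, rng_seed=2),
        )
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            simulated_annealing(lambda v: 0.0, [1.0], [1.0], self.CFG)


class TestObjective:
    def test_perfect_prediction_zero(self, noisefree_series, temps, latitude):
        obs, truth, _ = noisefree_series
        assert objective_rmse(truth.params, obs, temps, latitude) == pytest.approx(0.0, abs=0.51)
        # rounding of generated dates keeps the objective below half a day

    def test_known_residuals(self, obs_factory, temps, latitude):
        # craft observations at fixed offsets from the model's own dates
        truth = default_truth(rng_seed=0)
        pred = SeriesPredictor(temps, latitude, [2003, 2004]).predict(truth.params)
        obs = obs_factory(
            [int(pred[0]) + 3, int(pred[1]) - 4], years=[2003, 2004], station=temps.station_id
        )
        got = objective_rmse(truth.params, obs, temps, latitude)
        frac0 = pred[0] - int(pred[0])
        frac1 = pred[1] - int(pred[1])
        expect = np.sqrt(((3 - frac0) ** 2 + (4 + frac1) ** 2) / 2)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_non_occurrence_penalty_enters_mean(self, obs_factory, constant_temps):
        # threshold above the constant series: the trigger never fires
        params = make_parameters(
            ModelFamily.TPFORC, Trigger.TEMPERATURE, [15.0, -0.4, 10.0, 15.0]
        )
        obs = obs_factory([100, 100, 100], years=range(2000, 2003), station="CONST")
        got = objective_rmse(params, obs, constant_temps, 40.0)
        assert got == pytest.approx(NONOCCURRENCE_PENALTY_DAYS)


class TestGridOracle:
    def test_sa_matches_coarse_grid_on_tiny_instance(self, temps, latitude):
        """The annealer should do at least as well as a 10^4-point grid
        search (within 0.25 d) on a 5-year temperature-trigger instance."""
        truth = default_truth(Trigger.TEMPERATURE, observation_noise_sd=0.0, rng_seed=9)
        years = list(range(2005, 2010))
        obs, _ = generate_phenology(truth, temps, latitude, years)
        predictor = SeriesPredictor(temps, latitude, obs.years)
        observed = obs.doys

        def objective(vec):
            p = make_parameters(ModelFamily.TPFORC, Trigger.TEMPERATURE, vec)
            pred = predictor.predict(p)
            resid = np.where(np.isnan(pred), NONOCCURRENCE_PENALTY_DAYS, observed - pred)
            return float(np.sqrt(np.mean(resid**2)))

        # 10 x 10 x 10 x 10 grid over the default bounds
        bounds = ParameterBounds()
        lo, hi = bounds.arrays(ModelFamily.TPFORC, Trigger.TEMPERATURE)
        axes = [np.linspace(l, h, 10) for l, h in zip(lo, hi)]
        grid_best = min(objective(np.array(v)) for v in itertools.product(*axes))
        _, sa_best, _ = simulated_annealing(objective, lo, hi, SAConfig.small_budget(5))
        assert sa_best <= grid_best + 0.25


class TestFitModel:
    def test_noise_free_recovery_small_error(self, noisefree_series, temps, latitude):
        obs, truth, clean = noisefree_series
        t0 = time.time()
        fit = fit_model(
            ModelFamily.TPFORC, Trigger.PHOTOPERIOD, obs, temps, latitude,
            config=SAConfig.small_budget(11),
        )
        assert time.time() - t0 < 60.0  # single fit well within interactive budget
        assert fit.rmse <= 1.0  # dates quantised to whole days bound the floor
        pred = [fit.predictions[y] for y in clean]
        assert np.sqrt(np.mean((np.array(pred) - np.array(list(clean.values()))) ** 2)) <= 2.0

    def test_metrics_present_and_consistent(self, noisefree_series, temps, latitude):
        obs, _, _ = noisefree_series
        fit = fit_model(
            ModelFamily.UNIFORC, None, obs, temps, latitude, config=SAConfig.small_budget(3)
        )
        assert fit.k_params == 3 and fit.n_years == len(obs)
        assert fit.rmse >= 0 and fit.nse <= 1 and abs(fit.pearson_r) <= 1

    def test_short_series_rejected(self, obs_factory, temps, latitude):
        obs = obs_factory([100, 101, 102, 103, 104, 105], station=temps.station_id)
        with pytest.raises(ValueError, match="n > k"):
            fit_model(ModelFamily.TPFORC, Trigger.TEMPERATURE, obs, temps, latitude)

    def test_fitted_params_within_bounds(self, noisefree_series, temps, latitude):
        obs, _, _ = noisefree_series
        bounds = ParameterBounds()
        fit = fit_model(
            ModelFamily.TPFORC, Trigger.PHOTOPERIOD, obs, temps, latitude,
            bounds=bounds, config=SAConfig.small_budget(4),
        )
        lo, hi = bounds.arrays(ModelFamily.TPFORC, Trigger.PHOTOPERIOD)
        vec = [fit.params.p_start, fit.params.f_a, fit.params.f_b, fit.params.f_star]
        assert np.all(np.asarray(vec) >= lo) and np.all(np.asarray(vec) <= hi)


class TestSelection:
    def test_lower_rmse_wins_and_tie_goes_to_photoperiod(self, noisefree_series, temps, latitude):
        obs, _, _ = noisefree_series
        import dataclasses
        fit_t = fit_model(
            ModelFamily.TPFORC, Trigger.TEMPERATURE, obs, temps, latitude,
            config=SAConfig.small_budget(6),
        )
        fit_p = fit_model(
            ModelFamily.TPFORC, Trigger.PHOTOPERIOD, obs, temps, latitude,
            config=SAConfig.small_budget(7),
        )
        chosen, label = select_optimum_tpforc(
            dataclasses.replace(fit_t, rmse=4.0), dataclasses.replace(fit_p, rmse=5.0)
        )
        assert label is Trigger.TEMPERATURE and chosen.rmse == 4.0
        chosen, label = select_optimum_tpforc(
            dataclasses.replace(fit_t, rmse=5.0), dataclasses.replace(fit_p, rmse=4.0)
        )
        assert label is Trigger.PHOTOPERIOD
        chosen, label = select_optimum_tpforc(
            dataclasses.replace(fit_t, rmse=4.0), dataclasses.replace(fit_p, rmse=4.0)
        )
        assert label is Trigger.PHOTOPERIOD  # documented tie-break

    def test_wrong_trigger_order_rejected(self, noisefree_series, temps, latitude):
        obs, _, _ = noisefree_series
        fit_p = fit_model(
            ModelFamily.TPFORC, Trigger.PHOTOPERIOD, obs, temps, latitude,
            config=SAConfig.small_budget(8),
        )
        with pytest.raises(ValueError):
            select_optimum_tpforc(fit_p, fit_p)


def test_bounds_validation():
    with pytest.raises(ValueError):
        ParameterBounds({"f_a": (1.0, -1.0)})
    merged = ParameterBounds.from_dict({"t_start": [0, 10]})
    assert merged.intervals["t_start"] == (0.0, 10.0)
    assert merged.intervals["f_star"] == (1.0, 200.0)


def test_sa_config_validation():
    with pytest.raises(ValueError):
        SAConfig(cooling_factor=1.5)
    with pytest.raises(ValueError):
        SAConfig(n_restarts=0)
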
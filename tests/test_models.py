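import datetime
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tpforc.drivers import DaylengthModelConfig, daylength
from tpforc.io import DailyTemperatureSeries
from tpforc.models import (
    ComparisonModelParameters,
    ModelFamily,
    SeriesPredictor,
    TPForcParameters,
    Trigger,
    accumulate_forcing,
    bud_growth_rate,
    find_start_date_photoperiod,
    find_start_date_temperature,
    make_parameters,
    n_free_parameters,
    parameter_names,
    parameters_from_json,
    parameters_to_json,
    predict_series,
)


def tp(trigger="temperature", threshold=5.0, f_a=-0.4, f_b=10.0, f_star=15.0):
    key = "t_start" if trigger == "temperature" else "p_start"
    return TPForcParameters(trigger=Trigger(trigger), f_a=f_a, f_b=f_b, f_star=f_star,
                            **{key: threshold})


class TestBudGrowthRate:
    def test_midpoint_is_half(self):
        assert bud_growth_rate(10.0, -0.5, 10.0) == pytest.approx(0.5)

    def test_saturates_without_overflow(self):
        assert bud_growth_rate(1e6, -0.5, 10.0) == pytest.approx(1.0)
        assert bud_growth_rate(-1e6, -0.5, 10.0) == pytest.approx(0.0)
        assert bud_growth_rate(-1e9, -2.0, 30.0) < 1e-290  # padded-cell regime

    def test_analytic_three_quarters_point(self):
        # 1/(1+exp(-0.5 x)) = 0.75  =>  x = 2 ln 3
        T = 10.0 + 2.0 * math.log(3.0)
        assert bud_growth_rate(T, -0.5, 10.0) == pytest.approx(0.75, abs=1e-12)

    @given(st.floats(-30, 45), st.floats(-30, 45))
    def test_strictly_increasing_in_temperature(self, t1, t2):
        if abs(t1 - t2) < 1e-6:
            return
        lo, hi = sorted((t1, t2))
        assert bud_growth_rate(lo, -0.3, 8.0) < bud_growth_rate(hi, -0.3, 8.0)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            bud_growth_rate(10.0, 0.5, 10.0)


class TestStartDates:
    def test_constant_warm_fires_on_jan_21(self, constant_temps):
        assert find_start_date_temperature(constant_temps, 5.0, 2000) == datetime.date(2000, 1, 21)

    def test_never_fires_returns_none(self, constant_temps):
        assert find_start_date_temperature(constant_temps, 15.0, 2000) is None

    def test_ramp_crossing_matches_bruteforce(self):
        start = datetime.date(2000, 1, 1)
        n = 366
        values = np.linspace(-10, 25, n)  # monotone ramp through the year
        temps = DailyTemperatureSeries("R", start, values)
        got = find_start_date_temperature(temps, 0.0, 2000)
        d = datetime.date(2000, 1, 21)
        while temps.value_on(d) <= 0.0:
            d += datetime.timedelta(days=1)
        assert got == d

    def test_photoperiod_below_solstice_fires_next_day(self):
        # daylength at 40 N never drops below ~9 h; threshold 8 h fires
        # on the first searched day, 22 Dec of the previous year
        got = find_start_date_photoperiod(40.0, 8.0, 2000)
        assert got == datetime.date(1999, 12, 22)

    def test_photoperiod_above_maximum_is_none(self):
        assert find_start_date_photoperiod(40.0, 16.0, 2000) is None

    def test_photoperiod_threshold_matches_bruteforce_scan(self):
        got = find_start_date_photoperiod(40.0, 12.0, 2000)
        d = datetime.date(1999, 12, 22)
        while daylength(40.0, d.timetuple().tm_yday) <= 12.0:
            d += datetime.timedelta(days=1)
        assert got == d
        assert got.month == 3  # near the spring equinox

    def test_photoperiod_start_independent_of_temperature(self, constant_temps):
        params = tp("photoperiod", 12.0)
        traj = accumulate_forcing(constant_temps, params, 40.0, 2000)
        assert traj.start_date == find_start_date_photoperiod(40.0, 12.0, 2000)


class TestAccumulateForcing:
    def test_constant_rate_closed_form(self, constant_temps):
        # constant 10 degC with midpoint 10 gives rate exactly 0.5/day
        params = tp("temperature", 5.0, f_a=-0.4, f_b=10.0, f_star=5.0)
        traj = accumulate_forcing(constant_temps, params, 40.0, 2000)
        # 10 inclusive days of 0.5 reach 5.0
        assert traj.predicted_date == traj.start_date + datetime.timedelta(days=9)

    def test_tiny_requirement_met_on_start_day(self, constant_temps):
        params = tp("temperature", 5.0, f_star=0.25)
        traj = accumulate_forcing(constant_temps, params, 40.0, 2000)
        assert traj.predicted_date == traj.start_date

    def test_non_occurrence_flagged(self, constant_temps):
        params = tp("temperature", 15.0)
        traj = accumulate_forcing(constant_temps, params, 40.0, 2000)
        assert traj.start_date is None and not traj.occurred

    def test_cumulative_non_decreasing(self, temps):
        traj = accumulate_forcing(temps, tp("temperature", 5.0), 40.0, 2005)
        assert np.all(np.diff(traj.cumulative) >= 0)

    def test_matches_bruteforce_daily_loop(self, temps, latitude):
        rng = np.random.default_rng(42)
        for _ in range(25):
            trigger = rng.choice(["temperature", "photoperiod"])
            threshold = rng.uniform(-2, 8) if trigger == "temperature" else rng.uniform(9, 14)
            params = tp(
                trigger, threshold,
                f_a=-rng.uniform(0.1, 1.0), f_b=rng.uniform(2, 15), f_star=rng.uniform(3, 40),
            )
            year = int(rng.integers(2001, 2011))
            traj = accumulate_forcing(temps, params, latitude, year)
            # independent day-by-day scan
            if trigger == "temperature":
                d, found = datetime.date(year, 1, 21), None
                while d <= datetime.date(year, 12, 31):
                    if temps.value_on(d) > threshold:
                        found = d
                        break
                    d += datetime.timedelta(days=1)
            else:
                d = datetime.date(year - 1, 1, 1) + datetime.timedelta(days=354 + 1)
                found = None
                while d <= datetime.date(year, 12, 31):
                    if daylength(latitude, d.timetuple().tm_yday) > threshold:
                        found = d
                        break
                    d += datetime.timedelta(days=1)
            assert traj.start_date == found
            if found is None:
                continue
            acc, d, event = 0.0, found, None
            while d <= datetime.date(year, 12, 31):
                acc += 1.0 / (1.0 + math.exp(params.f_a * (temps.value_on(d) - params.f_b)))
                if acc >= params.f_star:
                    event = d
                    break
                d += datetime.timedelta(days=1)
            assert traj.predicted_date == event
            if event is not None:
                i = (event - found).days
                assert traj.cumulative[i] == pytest.approx(acc, abs=1e-9)


class TestPredictSeries:
    def test_matrix_predictor_agrees_with_scalar_path(self, temps, latitude, weather_config):
        years = weather_config.years
        params = tp("photoperiod", 12.0, f_b=5.0)
        by_matrix = predict_series(params, temps, latitude, years)
        for year in years:
            traj = accumulate_forcing(temps, params, latitude, year)
            expect = (
                None if traj.predicted_date is None
                else (traj.predicted_date - datetime.date(year, 1, 1)).days + 1
            )
            assert by_matrix[year] == expect

    def test_noise_free_self_consistency(self, noisefree_series, temps, latitude):
        obs, truth, clean = noisefree_series
        pred = predict_series(truth.params, temps, latitude, list(clean))
        for year, doy in clean.items():
            assert pred[year] == pytest.approx(doy)

    def test_m1_base_above_all_temperatures_never_occurs(self, temps, latitude):
        params = ComparisonModelParameters(ModelFamily.M1, f_star=10.0, t_base=60.0)
        pred = predict_series(params, temps, latitude, [2003, 2004])
        assert all(v is None for v in pred.values())

    def test_photothermal_not_earlier_than_uniforc(self, temps, latitude):
        shared = dict(f_a=-0.3, f_b=8.0, f_star=20.0)
        uni = ComparisonModelParameters(ModelFamily.UNIFORC, **shared)
        pho = ComparisonModelParameters(ModelFamily.PHOTOTHERMAL, **shared)
        pu = predict_series(uni, temps, latitude, [2002, 2006, 2009])
        pp = predict_series(pho, temps, latitude, [2002, 2006, 2009])
        for y in pu:
            if pu[y] is not None and pp[y] is not None:
                assert pp[y] >= pu[y]

    def test_comparison_models_start_jan_1(self, constant_temps):
        # high enough rate that the event lands within days of the anchor
        uni = ComparisonModelParameters(ModelFamily.UNIFORC, f_a=-2.0, f_b=0.1, f_star=2.5)
        pred = predict_series(uni, constant_temps, 40.0, [2000])
        assert pred[2000] == 3.0  # rate ~1/day from 1 Jan, F*=2.5 crossed on DOY 3


class TestMonotonicityProperties:
    families = [
        tp("temperature", 4.0, f_b=5.0, f_star=12.0),
        tp("photoperiod", 11.5, f_b=5.0, f_star=12.0),
        ComparisonModelParameters(ModelFamily.UNIFORC, f_a=-0.4, f_b=5.0, f_star=12.0),
        ComparisonModelParameters(ModelFamily.PHOTOTHERMAL, f_a=-0.4, f_b=5.0, f_star=12.0),
        ComparisonModelParameters(ModelFamily.M1, t_base=0.0, f_star=150.0),
    ]

    @pytest.mark.parametrize("params", families, ids=lambda p: getattr(p, "family", ModelFamily.TPFORC).value + getattr(p, "trigger", Trigger.TEMPERATURE).value[:1])
    def test_larger_requirement_delays_event(self, params, temps, latitude):
        import dataclasses

        years = [2003, 2007, 2010]
        small = predict_series(params, temps, latitude, years)
        big = predict_series(dataclasses.replace(params, f_star=params.f_star * 1.5),
                             temps, latitude, years)
        for y in years:
            if small[y] is not None and big[y] is not None:
                assert big[y] >= small[y]

    @pytest.mark.parametrize("params", families, ids=lambda p: getattr(p, "family", ModelFamily.TPFORC).value + getattr(p, "trigger", Trigger.TEMPERATURE).value[:1])
    def test_uniform_warming_advances_event(self, params, temps, latitude, weather_config):
        years = [2003, 2007, 2010]
        warm = DailyTemperatureSeries(temps.station_id, temps.start_date, temps.values + 2.0)
        base_pred = predict_series(params, temps, latitude, years)
        warm_pred = predict_series(params, warm, latitude, years)
        for y in years:
            if base_pred[y] is not None:
                assert warm_pred[y] is not None and warm_pred[y] <= base_pred[y]


class TestParameterPlumbing:
    def test_counts(self):
        assert n_free_parameters(ModelFamily.TPFORC, Trigger.TEMPERATURE) == 4
        assert n_free_parameters(ModelFamily.TPFORC, Trigger.PHOTOPERIOD) == 4
        assert n_free_parameters(ModelFamily.UNIFORC) == 3
        assert n_free_parameters(ModelFamily.PHOTOTHERMAL) == 3
        assert n_free_parameters(ModelFamily.M1) == 2

    def test_vector_roundtrip(self):
        for family, trigger in [
            (ModelFamily.TPFORC, Trigger.TEMPERATURE),
            (ModelFamily.TPFORC, Trigger.PHOTOPERIOD),
            (ModelFamily.UNIFORC, None),
            (ModelFamily.M1, None),
        ]:
            names = parameter_names(family, trigger)
            vec = {"t_start": 5.0, "p_start": 12.0, "f_a": -0.4, "f_b": 8.0,
                   "f_star": 20.0, "t_base": 2.0}
            params = make_parameters(family, trigger, [vec[n] for n in names])
            again = parameters_from_json(parameters_to_json(params))
            assert again == params

    def test_sign_constraints_enforced(self):
        with pytest.raises(ValueError):
            TPForcParameters(trigger=Trigger.TEMPERATURE, t_start=5.0, f_a=0.4, f_b=10.0, f_star=15.0)
        with pytest.raises(ValueError):
            TPForcParameters(trigger=Trigger.TEMPERATURE, t_start=5.0, p_start=12.0,
                             f_a=-0.4, f_b=10.0, f_star=15.0)
        with pytest.raises(ValueError):
            ComparisonModelParameters(ModelFamily.M1, f_star=-1.0, t_base=0.0)
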
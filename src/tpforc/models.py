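"""Forward spring-phenology models.

The two-trigger forcing model predicts the date of a spring phenophase
(first leaf unfolding or first flowering) in three steps:

1. Bud growth starts on date ``D_start``: either the first day after the
   climatological coldest date (20 January) on which daily mean air
   temperature exceeds a threshold ``T_start`` (temperature trigger), or
   the first day after the previous winter solstice on which daylength
   exceeds a threshold ``P_start`` (photoperiod trigger).
2. From ``D_start`` onward, each day contributes a bud growth rate that
   is a decreasing-logistic (sigmoid) function of daily mean temperature:
   ``R_f(T) = 1 / (1 + exp(f_a (T - f_b)))`` with slope ``f_a < 0`` and
   midpoint ``f_b > 0``.
3. The phenophase occurs on the first date on which the accumulated rate
   reaches the forcing requirement ``F*``.

Three one-phase comparison models share the accumulation machinery but
start on a prescribed date (1 January):

* uniforc      -- sigmoid forcing only (3 free parameters),
* photothermal -- sigmoid forcing weighted by the daylength fraction of
  the 24-h day (3 free parameters),
* m1           -- growing-degree accumulation above a base temperature,
  scaled by daylength / 10 h (2 free parameters).

A prediction can fail to occur (the requirement is never met by 31
December, or the trigger never fires); non-occurrence is represented as
``None`` (scalar API) or NaN (vector API), never as an exception.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .drivers import DaylengthModelConfig, WINTER_SOLSTICE_DOY, daylength
from .io import DailyTemperatureSeries, DataError

__all__ = [
    "ModelFamily",
    "Trigger",
    "TPForcParameters",
    "ComparisonModelParameters",
    "ForcingTrajectory",
    "bud_growth_rate",
    "find_start_date_temperature",
    "find_start_date_photoperiod",
    "accumulate_forcing",
    "predict_series",
    "SeriesPredictor",
    "n_free_parameters",
    "parameter_names",
    "make_parameters",
    "parameters_to_dict",
    "parameters_from_dict",
]

_EXP_CLIP = 700.0  # exp overflow guard; saturates the sigmoid instead
_PAD_TEMPERATURE = -1.0e9  # sentinel temperature for padded matrix cells


class ModelFamily(str, Enum):
    TPFORC = "tpforc"
    UNIFORC = "uniforc"
    PHOTOTHERMAL = "photothermal"
    M1 = "m1"


class Trigger(str, Enum):
    TEMPERATURE = "temperature"
    PHOTOPERIOD = "photoperiod"


@dataclass(frozen=True)
class TPForcParameters:
    """Parameters of the two-trigger forcing model.

    Exactly one of ``t_start`` / ``p_start`` is active, selected by
    ``trigger``; together with ``f_a``, ``f_b`` and ``f_star`` the model
    has four fitted parameters.
    """

    trigger: Trigger
    f_a: float
    f_b: float
    f_star: float
    t_start: float | None = None  # degC, temperature trigger only
    p_start: float | None = None  # hours, photoperiod trigger only

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger", Trigger(self.trigger))
        if self.f_a >= 0:
            raise ValueError("sigmoid slope f_a must be negative")
        if self.f_b <= 0:
            raise ValueError("sigmoid midpoint f_b must be positive")
        if self.f_star <= 0:
            raise ValueError("forcing requirement F* must be positive")
        if self.trigger is Trigger.TEMPERATURE:
            if self.t_start is None or self.p_start is not None:
                raise ValueError("temperature trigger requires t_start only")
        else:
            if self.p_start is None or self.t_start is not None:
                raise ValueError("photoperiod trigger requires p_start only")

    @property
    def threshold(self) -> float:
        return self.t_start if self.trigger is Trigger.TEMPERATURE else self.p_start


@dataclass(frozen=True)
class ComparisonModelParameters:
    """Parameters of the one-phase comparison models (fixed 1 January start)."""

    family: ModelFamily
    f_star: float
    f_a: float | None = None
    f_b: float | None = None
    t_base: float | None = None  # degC, m1 only

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        if self.family is ModelFamily.TPFORC:
            raise ValueError("use TPForcParameters for the two-trigger model")
        if self.f_star <= 0:
            raise ValueError("forcing requirement F* must be positive")
        if self.family in (ModelFamily.UNIFORC, ModelFamily.PHOTOTHERMAL):
            if self.f_a is None or self.f_b is None:
                raise ValueError(f"{self.family.value} requires f_a and f_b")
            if self.f_a >= 0:
                raise ValueError("sigmoid slope f_a must be negative")
        else:  # m1
            if self.t_base is None:
                raise ValueError("m1 requires t_base")


AnyParameters = TPForcParameters | ComparisonModelParameters


@dataclass
class ForcingTrajectory:
    """Day-by-day forcing accumulation for one phenology year."""

    start_date: datetime.date | None
    dates: list[datetime.date] = field(default_factory=list)
    daily_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    cumulative: np.ndarray = field(default_factory=lambda: np.empty(0))
    predicted_date: datetime.date | None = None

    @property
    def occurred(self) -> bool:
        return self.predicted_date is not None


# ---------------------------------------------------------------------------
# Elemental operations
# ---------------------------------------------------------------------------


def bud_growth_rate(temperature, f_a: float, f_b: float):
    """Sigmoid daily bud growth rate in (0, 1); vectorised over temperature."""
    if f_a >= 0:
        raise ValueError("sigmoid slope f_a must be negative")
    z = np.clip(f_a * (np.asarray(temperature, dtype=float) - f_b), -_EXP_CLIP, _EXP_CLIP)
    rate = 1.0 / (1.0 + np.exp(z))
    return float(rate) if rate.ndim == 0 else rate


def _doy_date(year: int, doy: int) -> datetime.date:
    return datetime.date(year, 1, 1) + datetime.timedelta(days=doy - 1)


def find_start_date_temperature(
    temps: DailyTemperatureSeries, t_start: float, year: int
) -> datetime.date | None:
    """First day strictly after 20 January of ``year`` with T > ``t_start``;
    None if no day up to 31 December qualifies."""
    first = datetime.date(year, 1, 21)
    last = min(datetime.date(year, 12, 31), temps.end_date)
    if last < first:
        raise DataError(f"no temperature coverage after 20 Jan {year}")
    window = temps.window(first, last)
    hits = np.nonzero(window > t_start)[0]
    if hits.size == 0:
        return None if last == datetime.date(year, 12, 31) else _raise_coverage(year, temps)
    return first + datetime.timedelta(days=int(hits[0]))


def _raise_coverage(year: int, temps: DailyTemperatureSeries):
    raise DataError(
        f"temperature series for station {temps.station_id} ends {temps.end_date}, "
        f"before 31 Dec {year}; cannot decide non-occurrence"
    )


def find_start_date_photoperiod(
    latitude: float,
    p_start: float,
    year: int,
    config: DaylengthModelConfig = DaylengthModelConfig(),
) -> datetime.date | None:
    """First day strictly after the previous winter solstice (day 355 of
    ``year - 1``) with daylength > ``p_start``; None if never reached by
    31 December of ``year``."""
    begin = _doy_date(year - 1, WINTER_SOLSTICE_DOY) + datetime.timedelta(days=1)
    end = datetime.date(year, 12, 31)
    n = (end - begin).days + 1
    dates = [begin + datetime.timedelta(days=i) for i in range(n)]
    doys = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    hours = daylength(latitude, doys, config)
    hits = np.nonzero(hours > p_start)[0]
    return dates[int(hits[0])] if hits.size else None


def accumulate_forcing(
    temps: DailyTemperatureSeries,
    params: TPForcParameters,
    latitude: float,
    year: int,
    config: DaylengthModelConfig = DaylengthModelConfig(),
) -> ForcingTrajectory:
    """Run the two-trigger model forward for one phenology year, returning
    the full daily trajectory (trigger date, rates, accumulation, event date)."""
    if params.trigger is Trigger.TEMPERATURE:
        start = find_start_date_temperature(temps, params.t_start, year)
    else:
        start = find_start_date_photoperiod(latitude, params.p_start, year, config)
    if start is None:
        return ForcingTrajectory(start_date=None)
    last = datetime.date(year, 12, 31)
    if temps.end_date < last:
        _raise_coverage(year, temps)
    window = temps.window(start, last)
    rates = bud_growth_rate(window, params.f_a, params.f_b)
    cumulative = np.cumsum(rates)
    dates = [start + datetime.timedelta(days=i) for i in range(len(window))]
    hits = np.nonzero(cumulative >= params.f_star)[0]
    predicted = dates[int(hits[0])] if hits.size else None
    return ForcingTrajectory(
        start_date=start,
        dates=dates,
        daily_rates=rates,
        cumulative=cumulative,
        predicted_date=predicted,
    )


# ---------------------------------------------------------------------------
# Vectorised multi-year predictor
# ---------------------------------------------------------------------------


class SeriesPredictor:
    """Pre-assembled temperature/daylength matrices for fast repeated
    prediction of the same station-years under different parameters.

    Each row is one phenology year, spanning 1 December of the previous
    year through 31 December of the year (the earliest admissible trigger
    date, the day after the previous winter solstice, falls inside this
    window).  Rows are right-padded with a sentinel so that padded cells
    contribute zero rate and can never host an event.
    """

    def __init__(
        self,
        temps: DailyTemperatureSeries,
        latitude: float,
        years: Sequence[int],
        config: DaylengthModelConfig = DaylengthModelConfig(),
    ) -> None:
        self.latitude = float(latitude)
        self.years = np.asarray(list(years), dtype=int)
        self.config = config
        n_years = len(self.years)
        starts = [datetime.date(y - 1, 12, 1) for y in self.years]
        n_days = np.array(
            [(datetime.date(y, 12, 31) - s).days + 1 for y, s in zip(self.years, starts)]
        )
        width = int(n_days.max())
        temp = np.full((n_years, width), _PAD_TEMPERATURE)
        dl = np.zeros((n_years, width))
        for i, (y, s, n) in enumerate(zip(self.years, starts, n_days)):
            temp[i, :n] = temps.window(s, datetime.date(int(y), 12, 31))
            doys = np.array(
                [(s + datetime.timedelta(days=int(j))).timetuple().tm_yday for j in range(n)],
                dtype=float,
            )
            dl[i, :n] = daylength(self.latitude, doys, config)
        cols = np.arange(width)
        self._temp = temp
        self._daylength = dl
        self._valid = cols[None, :] < n_days[:, None]
        self._n_days = n_days
        # column index of 1 Jan and of the first post-solstice day, per row
        self._jan1 = np.array(
            [(datetime.date(int(y), 1, 1) - s).days for y, s in zip(self.years, starts)]
        )
        self._post_solstice = np.array(
            [
                (_doy_date(int(y) - 1, WINTER_SOLSTICE_DOY) + datetime.timedelta(days=1) - s).days
                for y, s in zip(self.years, starts)
            ]
        )
        self._cols = cols

    # -- start-date machinery ------------------------------------------------

    def _first_true_at_or_after(self, condition: np.ndarray, from_col: np.ndarray) -> np.ndarray:
        """Per row, index of the first True at column >= from_col; -1 if none."""
        cond = condition & self._valid & (self._cols[None, :] >= from_col[:, None])
        fired = cond.any(axis=1)
        idx = np.argmax(cond, axis=1)
        return np.where(fired, idx, -1)

    def _start_indices(self, params: AnyParameters) -> np.ndarray:
        if isinstance(params, TPForcParameters):
            if params.trigger is Trigger.TEMPERATURE:
                # search begins 21 January, strictly after the coldest date
                return self._first_true_at_or_after(
                    self._temp > params.t_start, self._jan1 + 20
                )
            return self._first_true_at_or_after(
                self._daylength > params.p_start, self._post_solstice
            )
        return self._jan1.copy()  # comparison models accumulate from 1 January

    def _rates(self, params: AnyParameters) -> np.ndarray:
        if isinstance(params, TPForcParameters):
            return bud_growth_rate(self._temp, params.f_a, params.f_b)
        if params.family is ModelFamily.UNIFORC:
            return bud_growth_rate(self._temp, params.f_a, params.f_b)
        if params.family is ModelFamily.PHOTOTHERMAL:
            return (self._daylength / 24.0) * bud_growth_rate(
                self._temp, params.f_a, params.f_b
            )
        # m1: daylength-scaled growing degree days above t_base
        return (self._daylength / 10.0) * np.maximum(self._temp - params.t_base, 0.0)

    # -- prediction ----------------------------------------------------------

    def predict(self, params: AnyParameters) -> np.ndarray:
        """Predicted day of year per year (float); NaN marks non-occurrence.

        A date in December of the preceding year maps to DOY <= 0 (the
        continuous extension of the phenology-year axis).
        """
        start = self._start_indices(params)
        fired = start >= 0
        rates = self._rates(params)
        active = self._valid & (self._cols[None, :] >= np.where(fired, start, 10**9)[:, None])
        cum = np.cumsum(np.where(active, rates, 0.0), axis=1)
        crossed = (cum >= params.f_star) & active
        occurred = crossed.any(axis=1)
        idx = np.argmax(crossed, axis=1)
        doy = idx.astype(float) - (self._jan1 - 1)
        return np.where(fired & occurred, doy, np.nan)

    def predict_dict(self, params: AnyParameters) -> dict[int, float | None]:
        pred = self.predict(params)
        return {
            int(y): (None if np.isnan(p) else float(p)) for y, p in zip(self.years, pred)
        }


def predict_series(
    params: AnyParameters,
    temps: DailyTemperatureSeries,
    latitude: float,
    years: Sequence[int],
    config: DaylengthModelConfig = DaylengthModelConfig(),
) -> dict[int, float | None]:
    """Predict the phenophase day of year for each year; None marks
    non-occurrence (trigger never fired or requirement unmet by 31 Dec)."""
    return SeriesPredictor(temps, latitude, years, config).predict_dict(params)


# ---------------------------------------------------------------------------
# Parameter vector <-> dataclass plumbing (used by the calibrator)
# ---------------------------------------------------------------------------

_PARAM_NAMES: dict[tuple[ModelFamily, Trigger | None], tuple[str, ...]] = {
    (ModelFamily.TPFORC, Trigger.TEMPERATURE): ("t_start", "f_a", "f_b", "f_star"),
    (ModelFamily.TPFORC, Trigger.PHOTOPERIOD): ("p_start", "f_a", "f_b", "f_star"),
    (ModelFamily.UNIFORC, None): ("f_a", "f_b", "f_star"),
    (ModelFamily.PHOTOTHERMAL, None): ("f_a", "f_b", "f_star"),
    (ModelFamily.M1, None): ("t_base", "f_star"),
}


def parameter_names(family: ModelFamily, trigger: Trigger | None = None) -> tuple[str, ...]:
    family = ModelFamily(family)
    trigger = Trigger(trigger) if (trigger is not None and family is ModelFamily.TPFORC) else None
    if family is ModelFamily.TPFORC and trigger is None:
        raise ValueError("the two-trigger family needs an explicit trigger")
    return _PARAM_NAMES[(family, trigger)]


def n_free_parameters(family: ModelFamily, trigger: Trigger | None = None) -> int:
    """Number of fitted parameters, the k entering the information criterion."""
    return len(parameter_names(family, trigger))


def make_parameters(
    family: ModelFamily, trigger: Trigger | None, vector: Sequence[float]
) -> AnyParameters:
    """Build a parameter object from a flat vector in ``parameter_names`` order."""
    family = ModelFamily(family)
    names = parameter_names(family, trigger)
    if len(vector) != len(names):
        raise ValueError(f"expected {len(names)} values for {family.value}, got {len(vector)}")
    kwargs = dict(zip(names, (float(v) for v in vector)))
    if family is ModelFamily.TPFORC:
        return TPForcParameters(trigger=Trigger(trigger), **kwargs)
    return ComparisonModelParameters(family=family, **kwargs)


def parameters_to_dict(params: AnyParameters) -> dict:
    if isinstance(params, TPForcParameters):
        d = {k: v for k, v in asdict(params).items() if v is not None}
        d["family"] = ModelFamily.TPFORC.value
        d["trigger"] = params.trigger.value
        return d
    d = {k: v for k, v in asdict(params).items() if v is not None}
    d["family"] = params.family.value
    return d


def parameters_from_dict(d: Mapping) -> AnyParameters:
    d = dict(d)
    family = ModelFamily(d.pop("family"))
    if family is ModelFamily.TPFORC:
        return TPForcParameters(**d)
    return ComparisonModelParameters(family=family, **d)


def parameters_to_json(params: AnyParameters) -> str:
    return json.dumps(parameters_to_dict(params), indent=2, sort_keys=True)


def parameters_from_json(text: str) -> AnyParameters:
    return parameters_from_dict(json.loads(text))
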
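"""Photoperiod and derived climate covariates.

Daylength follows the revised-Schoolfield formulation of Forsythe et al.
(1995): solar declination is obtained from the day angle through the
revolution-angle expression, and day length from the sunset hour angle,
with a single coefficient ``p`` (degrees of solar elevation below the
horizon at which the day is considered to begin and end).  The default
p = 0.8333 deg corresponds to sunrise/sunset including atmospheric
refraction and the apparent radius of the solar disc.

The climate covariates summarise the thermal environment around the
phenological event: mean winter (Dec-Feb) temperature, winter duration
(days below 5 degC between 1 November and the mean event date), and the
short-term spring temperature variability (SD of linearly detrended
temperatures over the 60 days preceding the mean event date).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import DailyTemperatureSeries, DataError

__all__ = [
    "DaylengthModelConfig",
    "ClimateMetrics",
    "daylength",
    "winter_temperature",
    "winter_duration",
    "spring_temperature_variation",
    "climate_metrics",
    "WINTER_SOLSTICE_DOY",
    "SUMMER_SOLSTICE_DOY",
]

#: solstice days of year, non-leap convention
WINTER_SOLSTICE_DOY = 355
SUMMER_SOLSTICE_DOY = 172


@dataclass(frozen=True)
class DaylengthModelConfig:
    """Configuration of the daylength model.

    ``daylength_coefficient_p`` is in degrees; 0.8333 gives standard
    sunrise-to-sunset daylength, 0 the geometric (center-of-disc) day,
    6/12/18 the civil/nautical/astronomical twilight definitions.
    """

    daylength_coefficient_p: float = 0.8333

    def __post_init__(self) -> None:
        if not -6.0 <= self.daylength_coefficient_p <= 18.0:
            raise ValueError("daylength coefficient p outside [-6, 18] degrees")


_DEFAULT_CONFIG = DaylengthModelConfig()


def daylength(
    latitude: float,
    doy,
    config: DaylengthModelConfig = _DEFAULT_CONFIG,
):
    """Day length in hours at ``latitude`` (degrees north) on day(s) of year ``doy``.

    Vectorised over ``doy``.  The arccosine argument is clamped, so polar
    day and polar night return 24 h and 0 h rather than raising.
    """
    doy = np.asarray(doy, dtype=float)
    p = config.daylength_coefficient_p
    # revolution angle and solar declination (radians)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    decl = np.arcsin(0.39795 * np.cos(theta))
    lat = np.radians(latitude)
    num = np.sin(np.radians(p)) + np.sin(lat) * np.sin(decl)
    cos_arg = np.clip(num / (np.cos(lat) * np.cos(decl)), -1.0, 1.0)
    hours = 24.0 - (24.0 / np.pi) * np.arccos(cos_arg)
    return float(hours) if hours.ndim == 0 else hours


def _require_window(temps: DailyTemperatureSeries, first: datetime.date, last: datetime.date) -> np.ndarray:
    try:
        return temps.window(first, last)
    except DataError as exc:
        raise DataError(f"insufficient temperature coverage: {exc}") from None


def winter_temperature(temps: DailyTemperatureSeries, years: Iterable[int]) -> float:
    """Multiyear mean temperature from previous December through February.

    For each phenology year ``y`` the window runs 1 Dec (y-1) to the last
    day of Feb (y); the mean is taken over all days of all windows.
    """
    chunks = []
    for year in years:
        first = datetime.date(year - 1, 12, 1)
        last = datetime.date(year, 3, 1) - datetime.timedelta(days=1)
        chunks.append(_require_window(temps, first, last))
    if not chunks:
        raise ValueError("no years supplied")
    return float(np.concatenate(chunks).mean())


def _mean_event_date(year: int, mean_phenology_doy: int) -> datetime.date:
    return datetime.date(year, 1, 1) + datetime.timedelta(days=int(mean_phenology_doy) - 1)


def winter_duration(
    temps: DailyTemperatureSeries,
    mean_phenology_doy: int,
    years: Iterable[int],
    threshold: float = 5.0,
) -> float:
    """Mean number of days below ``threshold`` degC from 1 Nov (previous year)
    to the mean phenological date, averaged over ``years``."""
    counts = []
    for year in years:
        window = _require_window(
            temps, datetime.date(year - 1, 11, 1), _mean_event_date(year, mean_phenology_doy)
        )
        counts.append(int(np.sum(window < threshold)))
    if not counts:
        raise ValueError("no years supplied")
    return float(np.mean(counts))


def spring_temperature_variation(
    temps: DailyTemperatureSeries,
    mean_phenology_doy: int,
    years: Iterable[int],
    window_days: int = 60,
) -> float:
    """Multiyear mean SD of linearly detrended temperature over the
    ``window_days`` ending the day before the mean phenological date."""
    sds = []
    x = np.arange(window_days, dtype=float)
    for year in years:
        last = _mean_event_date(year, mean_phenology_doy) - datetime.timedelta(days=1)
        first = last - datetime.timedelta(days=window_days - 1)
        w = _require_window(temps, first, last)
        coeffs = np.polyfit(x, w, 1)
        resid = w - np.polyval(coeffs, x)
        sds.append(resid.std(ddof=1))
    if not sds:
        raise ValueError("no years supplied")
    return float(np.mean(sds))


@dataclass(frozen=True)
class ClimateMetrics:
    """Site-level climate covariates around a mean phenological date."""

    winter_temperature: float
    winter_duration: float
    spring_temperature_variation: float
    mean_phenology_doy: int


def climate_metrics(
    temps: DailyTemperatureSeries,
    observed_doys: Sequence[int],
    years: Sequence[int],
) -> ClimateMetrics:
    """Compute all three covariates for one series; the mean phenological
    date is the rounded multiyear mean of the observed days of year."""
    mean_doy = int(round(float(np.mean(observed_doys))))
    return ClimateMetrics(
        winter_temperature=winter_temperature(temps, years),
        winter_duration=winter_duration(temps, mean_doy, years),
        spring_temperature_variation=spring_temperature_variation(temps, mean_doy, years),
        mean_phenology_doy=mean_doy,
    )
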
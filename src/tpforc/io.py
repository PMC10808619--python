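"""Domain containers and CSV input/output for station phenology networks.

Three flat-file dialects are used throughout the package:

* temperatures: ``station_id,date,tmean`` (ISO dates, degrees Celsius)
* phenology:    ``station_id,species,phenophase,year,doy``
* stations:     ``station_id,lat,lon,elev,zone``

Series cleaning follows the screening applied to the Chinese phenology
network observations: observations farther than two standard deviations
from the series mean are discarded, and series shorter than ten years
after screening are rejected.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateZone",
    "Phenophase",
    "StationRecord",
    "DailyTemperatureSeries",
    "PhenologyObservationSeries",
    "CleaningReport",
    "FormatError",
    "DataError",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_phenology_csv",
    "write_phenology_csv",
    "read_station_csv",
    "write_station_csv",
    "remove_outliers",
    "filter_min_length",
    "clean_series",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class DataError(ValueError):
    """Structurally valid data violate a content requirement (gaps, coverage)."""


class ClimateZone(str, Enum):
    """Climatic zones of the eastern monsoon study region, ordered north to south."""

    MIDDLE_TEMPERATE = "middle_temperate"
    WARM_TEMPERATE = "warm_temperate"
    NORTH_SUBTROPICAL = "north_subtropical"
    MIDDLE_SUBTROPICAL = "middle_subtropical"
    SOUTH_SUBTROPICAL = "south_subtropical"
    NORTH_TROPICAL = "north_tropical"
    OTHER = "other"


#: north-to-south ordering used by zone summaries
ZONE_ORDER: tuple[ClimateZone, ...] = (
    ClimateZone.MIDDLE_TEMPERATE,
    ClimateZone.WARM_TEMPERATE,
    ClimateZone.NORTH_SUBTROPICAL,
    ClimateZone.MIDDLE_SUBTROPICAL,
    ClimateZone.SOUTH_SUBTROPICAL,
    ClimateZone.NORTH_TROPICAL,
)


class Phenophase(str, Enum):
    FIRST_LEAF_UNFOLDING = "first_leaf_unfolding"
    FIRST_FLOWERING = "first_flowering"


@dataclass(frozen=True)
class StationRecord:
    """One observation station: identifier, coordinates and climate zone."""

    station_id: str
    latitude: float
    longitude: float
    elevation: float
    climate_zone: ClimateZone = ClimateZone.OTHER

    def __post_init__(self) -> None:
        if not self.station_id:
            raise ValueError("station_id must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


@dataclass
class DailyTemperatureSeries:
    """Contiguous daily mean air temperature record for one station.

    ``values[i]`` is the mean temperature (degrees C) on
    ``start_date + i days``; there are no gaps by construction.
    """

    station_id: str
    start_date: datetime.date
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise DataError("temperature values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_date(self) -> datetime.date:
        return self.start_date + datetime.timedelta(days=len(self) - 1)

    def index_of(self, day: datetime.date) -> int:
        idx = (day - self.start_date).days
        if not 0 <= idx < len(self):
            raise DataError(
                f"date {day} outside coverage "
                f"[{self.start_date}, {self.end_date}] of station {self.station_id}"
            )
        return idx

    def value_on(self, day: datetime.date) -> float:
        return float(self.values[self.index_of(day)])

    def window(self, first: datetime.date, last: datetime.date) -> np.ndarray:
        """Temperatures on the inclusive date range ``[first, last]``."""
        if last < first:
            raise ValueError("window end precedes start")
        return self.values[self.index_of(first) : self.index_of(last) + 1]

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=len(self), freq="D")


@dataclass
class PhenologyObservationSeries:
    """Observed event dates (day of year) for one station, species and phenophase."""

    station_id: str
    species: str
    phenophase: Phenophase
    observations: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenophase = Phenophase(self.phenophase)
        for year, doy in self.observations.items():
            if not 1 <= doy <= 366:
                raise FormatError(f"day-of-year {doy} (year {year}) outside [1, 366]")
        self.observations = dict(sorted(self.observations.items()))

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def years(self) -> np.ndarray:
        return np.array(list(self.observations.keys()), dtype=int)

    @property
    def doys(self) -> np.ndarray:
        return np.array(list(self.observations.values()), dtype=float)

    def key(self) -> tuple[str, str, str]:
        return (self.station_id, self.species, self.phenophase.value)

    def replace_observations(self, obs: Mapping[int, int]) -> "PhenologyObservationSeries":
        return PhenologyObservationSeries(
            self.station_id, self.species, self.phenophase, dict(obs)
        )


@dataclass
class CleaningReport:
    """Bookkeeping for the outlier and series-length screening of one series."""

    series_key: tuple[str, str, str]
    removed_outliers: list[tuple[int, int]]
    removed_short_series: bool
    n_before: int
    n_after: int

    def to_dict(self) -> dict:
        return {
            "station_id": self.series_key[0],
            "species": self.series_key[1],
            "phenophase": self.series_key[2],
            "removed_outliers": [list(t) for t in self.removed_outliers],
            "removed_short_series": self.removed_short_series,
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_TEMP_COLS = ["station_id", "date", "tmean"]
_PHEN_COLS = ["station_id", "species", "phenophase", "year", "doy"]
_STATION_COLS = ["station_id", "lat", "lon", "elev", "zone"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_temperature_csv(
    path, station_id: str | None = None, fill_gaps: bool = False, max_gap_days: int = 3
) -> DailyTemperatureSeries:
    """Read one station's daily temperature series.

    Dates must be contiguous.  With ``fill_gaps`` enabled, gaps of at most
    ``max_gap_days`` missing days are filled by linear interpolation between
    the flanking observed days; longer gaps always raise :class:`DataError`.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TEMP_COLS, path)
    if station_id is not None:
        df = df[df["station_id"].astype(str) == str(station_id)]
    if df.empty:
        raise DataError(f"{path}: no temperature rows" + (f" for station {station_id}" if station_id else ""))
    sids = df["station_id"].astype(str).unique()
    if len(sids) > 1:
        raise FormatError(
            f"{path}: multiple stations {list(sids)}; pass station_id to select one"
        )
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable ISO dates: {exc}") from None
    series = pd.Series(df["tmean"].to_numpy(float), index=dates).sort_index()
    if series.index.has_duplicates:
        raise FormatError(f"{path}: duplicated dates for station {sids[0]}")
    full = pd.date_range(series.index[0], series.index[-1], freq="D")
    if len(full) != len(series):
        gap_lengths = np.diff(series.index.to_julian_date().astype(int)) - 1
        worst = int(gap_lengths.max())
        if not fill_gaps or worst > max_gap_days:
            raise DataError(
                f"{path}: temperature series has a {worst}-day gap "
                f"(fill_gaps={'on' if fill_gaps else 'off'}, limit {max_gap_days})"
            )
        series = series.reindex(full).interpolate(method="linear")
    values = series.to_numpy(float)
    if np.isnan(values).any():
        raise DataError(f"{path}: non-finite temperature values")
    return DailyTemperatureSeries(str(sids[0]), series.index[0].date(), values)


def read_temperature_network_csv(path, **kwargs) -> dict[str, DailyTemperatureSeries]:
    """Read a multi-station temperature CSV into a station_id -> series map."""
    df = pd.read_csv(path, usecols=lambda c: True)
    _require_columns(df, _TEMP_COLS, path)
    return {
        str(sid): read_temperature_csv(path, station_id=str(sid), **kwargs)
        for sid in df["station_id"].astype(str).unique()
    }


def write_temperature_csv(path, series: DailyTemperatureSeries | Iterable[DailyTemperatureSeries]) -> None:
    if isinstance(series, DailyTemperatureSeries):
        series = [series]
    frames = [
        pd.DataFrame(
            {
                "station_id": s.station_id,
                "date": s.dates().strftime("%Y-%m-%d"),
                "tmean": s.values,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_phenology_csv(path) -> list[PhenologyObservationSeries]:
    """Read phenology observations, one series per (station, species, phenophase)."""
    df = pd.read_csv(path)
    _require_columns(df, _PHEN_COLS, path)
    bad = df[(df["doy"] < 1) | (df["doy"] > 366)]
    if not bad.empty:
        row = bad.iloc[0]
        raise FormatError(f"{path}: day-of-year {row['doy']} (year {row['year']}) outside [1, 366]")
    out: list[PhenologyObservationSeries] = []
    for (sid, sp, ph), grp in df.groupby(["station_id", "species", "phenophase"], sort=True):
        if grp["year"].duplicated().any():
            raise FormatError(f"{path}: duplicate year for series ({sid}, {sp}, {ph})")
        obs = dict(zip(grp["year"].astype(int), grp["doy"].astype(int)))
        out.append(PhenologyObservationSeries(str(sid), str(sp), Phenophase(ph), obs))
    return out


def write_phenology_csv(path, series_list: Iterable[PhenologyObservationSeries]) -> None:
    rows = [
        {
            "station_id": s.station_id,
            "species": s.species,
            "phenophase": s.phenophase.value,
            "year": year,
            "doy": doy,
        }
        for s in series_list
        for year, doy in s.observations.items()
    ]
    pd.DataFrame(rows, columns=_PHEN_COLS).to_csv(path, index=False)


def read_station_csv(path) -> list[StationRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _STATION_COLS, path)
    if df["station_id"].astype(str).duplicated().any():
        raise FormatError(f"{path}: duplicated station_id")
    return [
        StationRecord(
            str(r.station_id),
            float(r.lat),
            float(r.lon),
            float(r.elev),
            ClimateZone(r.zone),
        )
        for r in df.itertuples()
    ]


def write_station_csv(path, stations: Iterable[StationRecord]) -> None:
    pd.DataFrame(
        [
            {
                "station_id": s.station_id,
                "lat": s.latitude,
                "lon": s.longitude,
                "elev": s.elevation,
                "zone": s.climate_zone.value,
            }
            for s in stations
        ],
        columns=_STATION_COLS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Series cleaning
# ---------------------------------------------------------------------------


def remove_outliers(
    series: PhenologyObservationSeries,
) -> tuple[PhenologyObservationSeries, CleaningReport]:
    """Drop observations more than two sample standard deviations from the mean.

    The mean and SD are computed once on the full input series (single pass);
    re-applying the screen with those same statistics is a no-op.  A constant
    series (SD = 0) is returned unchanged.
    """
    if len(series) < 3:
        raise ValueError("outlier screening needs at least 3 observations")
    doys = series.doys
    mean = doys.mean()
    sd = doys.std(ddof=1)
    keep = np.abs(doys - mean) <= 2.0 * sd
    removed = [
        (int(y), int(d)) for y, d, k in zip(series.years, doys, keep) if not k
    ]
    cleaned = series.replace_observations(
        {int(y): int(d) for y, d, k in zip(series.years, doys, keep) if k}
    )
    report = CleaningReport(
        series_key=series.key(),
        removed_outliers=removed,
        removed_short_series=False,
        n_before=len(series),
        n_after=len(cleaned),
    )
    return cleaned, report


def filter_min_length(
    series: PhenologyObservationSeries, min_years: int = 10
) -> PhenologyObservationSeries | None:
    """Return the series if it spans at least ``min_years`` observations, else None."""
    return series if len(series) >= min_years else None


def clean_series(
    series: PhenologyObservationSeries, min_years: int = 10
) -> tuple[PhenologyObservationSeries | None, CleaningReport]:
    """Full screening pipeline: outlier removal first, then the length filter."""
    cleaned, report = remove_outliers(series)
    kept = filter_min_length(cleaned, min_years=min_years)
    if kept is None:
        report.removed_short_series = True
    return kept, report


def write_cleaning_reports(path, reports: Iterable[CleaningReport]) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2) + "\n"
    )
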
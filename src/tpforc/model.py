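"""Model/Results front end for fitting spring phenology models.

`SpringPhenologyModel` binds one observed phenology series to its
station's daily temperatures and latitude; `fit()` calibrates the chosen
model family by simulated annealing and returns a `PhenologyResults`
carrying the estimates, per-year predictions, goodness-of-fit metrics
and a printable summary.  For the two-trigger family with no trigger
specified, both sub-models are fitted and the lower-RMSE one selected.

Example
-------
>>> from tpforc import SpringPhenologyModel, SAConfig
>>> from tpforc.synthetic import WeatherGenConfig, generate_temperature, \
...     generate_phenology, default_truth
>>> cfg = WeatherGenConfig(rng_seed=42)
>>> temps = generate_temperature(cfg)
>>> obs, _ = generate_phenology(default_truth(rng_seed=42), temps, 40.0, cfg.years)
>>> res = SpringPhenologyModel(obs, temps, latitude=40.0).fit(
...     config=SAConfig.small_budget(rng_seed=1))
>>> res.rmse < 5.0
True
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    FitResult,
    ParameterBounds,
    SAConfig,
    fit_model,
    select_optimum_tpforc,
)
from .evaluation import CrossValidationResult, loocv
from .io import DailyTemperatureSeries, PhenologyObservationSeries, Phenophase, clean_series
from .models import ModelFamily, SeriesPredictor, Trigger, parameters_to_dict

__all__ = ["SpringPhenologyModel", "PhenologyResults"]


class SpringPhenologyModel:
    """A spring phenology model bound to one observation series.

    Parameters
    ----------
    observations
        Cleaned event dates (year -> day of year) for one
        station-species-phenophase combination.
    temps
        Contiguous daily mean temperatures covering 1 December before the
        first observation year through 31 December of the last.
    latitude
        Station latitude, degrees north.
    family
        ``"tpforc"`` (default), ``"uniforc"``, ``"photothermal"`` or ``"m1"``.
    trigger
        For the two-trigger family: ``"temperature"``, ``"photoperiod"``,
        or None to fit both and select the lower-RMSE sub-model.
    """

    def __init__(
        self,
        observations: PhenologyObservationSeries,
        temps: DailyTemperatureSeries,
        latitude: float,
        family: ModelFamily | str = ModelFamily.TPFORC,
        trigger: Trigger | str | None = None,
        bounds: ParameterBounds | None = None,
    ) -> None:
        self.observations = observations
        self.temps = temps
        self.latitude = float(latitude)
        self.family = ModelFamily(family)
        self.trigger = Trigger(trigger) if trigger is not None else None
        self.bounds = bounds if bounds is not None else ParameterBounds()

    @classmethod
    def from_dataframes(
        cls,
        phenology: pd.DataFrame,
        temperatures: pd.DataFrame,
        latitude: float,
        clean: bool = True,
        **kwargs,
    ) -> "SpringPhenologyModel":
        """Build from tidy frames: phenology with columns
        ``station_id, species, phenophase, year, doy`` (one series) and
        temperatures with ``station_id, date, tmean``.  With ``clean``
        enabled the standard screening (2-SD outliers, >= 10 years) is
        applied first."""
        required = {"station_id", "species", "phenophase", "year", "doy"}
        if not required.issubset(phenology.columns):
            raise ValueError(f"phenology frame needs columns {sorted(required)}")
        keys = phenology[["station_id", "species", "phenophase"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError("phenology frame must contain exactly one series")
        sid, species, phase = keys.iloc[0]
        obs = PhenologyObservationSeries(
            str(sid),
            str(species),
            Phenophase(phase),
            dict(zip(phenology["year"].astype(int), phenology["doy"].astype(int))),
        )
        if clean:
            cleaned, _ = clean_series(obs)
            if cleaned is None:
                raise ValueError("series shorter than 10 years after screening")
            obs = cleaned
        tf = temperatures[temperatures["station_id"].astype(str) == str(sid)]
        dates = pd.to_datetime(tf["date"])
        tf = tf.assign(_d=dates).sort_values("_d")
        full = pd.date_range(tf["_d"].iloc[0], tf["_d"].iloc[-1], freq="D")
        if len(full) != len(tf):
            raise ValueError("temperature frame has date gaps")
        temps = DailyTemperatureSeries(
            str(sid), tf["_d"].iloc[0].date(), tf["tmean"].to_numpy(float)
        )
        return cls(obs, temps, latitude, **kwargs)

    def fit(
        self, config: SAConfig | None = None, seed: int | None = None
    ) -> "PhenologyResults":
        """Calibrate by simulated annealing and score the fit."""
        config = config if config is not None else SAConfig()
        if seed is not None:
            config = config.with_seed(seed)
        if self.family is ModelFamily.TPFORC and self.trigger is None:
            fit_t = fit_model(
                ModelFamily.TPFORC, Trigger.TEMPERATURE,
                self.observations, self.temps, self.latitude,
                bounds=self.bounds, config=config,
            )
            fit_p = fit_model(
                ModelFamily.TPFORC, Trigger.PHOTOPERIOD,
                self.observations, self.temps, self.latitude,
                bounds=self.bounds, config=config.with_seed(config.rng_seed + 1),
            )
            best, _ = select_optimum_tpforc(fit_t, fit_p)
            return PhenologyResults(self, best, fit_t=fit_t, fit_p=fit_p)
        result = fit_model(
            self.family, self.trigger,
            self.observations, self.temps, self.latitude,
            bounds=self.bounds, config=config,
        )
        return PhenologyResults(self, result)

    def predict(self, params, years=None) -> dict[int, float | None]:
        """Forward-run arbitrary parameters over the observation years
        (or an explicit year list)."""
        years = list(self.observations.years) if years is None else list(years)
        return SeriesPredictor(self.temps, self.latitude, years).predict_dict(params)


@dataclass
class PhenologyResults:
    """Fitted-model results: estimates, predictions, metrics, diagnostics."""

    model: SpringPhenologyModel
    fit: FitResult
    fit_t: FitResult | None = None
    fit_p: FitResult | None = None
    _cv: CrossValidationResult | None = field(default=None, repr=False)

    # -- pass-through conveniences ------------------------------------------

    @property
    def params(self):
        return self.fit.params

    @property
    def selected_trigger(self) -> Trigger | None:
        return self.fit.trigger

    @property
    def predictions(self) -> dict[int, float | None]:
        return self.fit.predictions

    @property
    def rmse(self) -> float:
        return self.fit.rmse

    @property
    def nse(self) -> float:
        return self.fit.nse

    @property
    def aicc(self) -> float:
        return self.fit.aicc

    @property
    def pearson_r(self) -> float:
        return self.fit.pearson_r

    @property
    def pearson_p(self) -> float:
        return self.fit.pearson_p

    def residuals(self) -> pd.Series:
        obs = self.model.observations
        pred = self.fit.predictions
        return pd.Series(
            {y: (obs.observations[y] - pred[y]) if pred[y] is not None else np.nan
             for y in obs.observations},
            name="residual_days",
        )

    def crossval(
        self, config: SAConfig | None = None, min_fold_years: int = 10
    ) -> CrossValidationResult:
        """Leave-one-out cross-validation of the selected model."""
        cv = loocv(
            self.fit.family,
            self.fit.trigger,
            self.model.observations,
            self.model.temps,
            self.model.latitude,
            bounds=self.model.bounds,
            config=config,
            min_fold_years=min_fold_years,
        )
        self._cv = cv
        return cv

    def summary(self) -> str:
        """A printable statsmodels-style summary table."""
        obs = self.model.observations
        lines = [
            "Spring Phenology Model Results",
            "=" * 46,
            f"{'Series:':<24}{obs.station_id}/{obs.species}/{obs.phenophase.value}",
            f"{'Model:':<24}{self.fit.label}",
            f"{'No. years:':<24}{self.fit.n_years}",
            f"{'No. parameters (k):':<24}{self.fit.k_params}",
            "-" * 46,
        ]
        for name, value in parameters_to_dict(self.fit.params).items():
            if isinstance(value, float):
                lines.append(f"{name:<24}{value:>12.4f}")
        lines.append("-" * 46)
        nse_txt = f"{self.nse:>12.4f}" if np.isfinite(self.nse) else "   undefined"
        lines += [
            f"{'RMSE (days)':<24}{self.rmse:>12.4f}",
            f"{'NSE':<24}{nse_txt}",
            f"{'AICc':<24}{self.aicc:>12.4f}",
            f"{'Pearson r':<24}{self.pearson_r:>12.4f}",
            f"{'Pearson p':<24}{self.pearson_p:>12.4g}",
        ]
        if self.fit_t is not None and self.fit_p is not None:
            lines += [
                "-" * 46,
                f"{'RMSE temperature sub-model':<32}{self.fit_t.rmse:>10.4f}",
                f"{'RMSE photoperiod sub-model':<32}{self.fit_p.rmse:>10.4f}",
                f"{'Selected trigger':<32}{self.fit.trigger.value:>10}",
            ]
        if self._cv is not None:
            lines.append(f"{'VRMSE (LOOCV, days)':<24}{self._cv.vrmse:>12.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.fit.to_dict()
        if self._cv is not None:
            d["loocv"] = self._cv.to_dict()
        return d

    def plot_fit(self, ax=None):
        """Observed vs fitted dates over years (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.observations
        years = list(obs.observations)
        ax.plot(years, [obs.observations[y] for y in years], "o-", label="observed")
        ax.plot(
            years,
            [self.fit.predictions[y] for y in years],
            "s--",
            label=f"fitted ({self.fit.label})",
        )
        ax.set_xlabel("year")
        ax.set_ylabel("day of year")
        ax.legend()
        return ax
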
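"""Goodness-of-fit metrics, cross-validation and summary tables.

Metrics:

* RMSE  -- root mean squared error between observed and fitted dates.
* NSE   -- Nash-Sutcliffe efficiency, 1 - SSE / SS_about_observed_mean;
  1 is a perfect fit, 0 matches the null model that always predicts the
  observed mean date, negative is worse than the null model.
* AICc  -- small-sample corrected Akaike information criterion,
  ``n ln(SSE/n) + 2 n (k+1) / (n - k - 2)`` for k fitted parameters.
* Pearson r with its two-sided significance.

Leave-one-out cross-validation refits the model n times, each time
withholding one year and predicting it from the remaining n-1 years; the
validation RMSE (VRMSE) is computed across the n held-out predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DailyTemperatureSeries, PhenologyObservationSeries, ZONE_ORDER, ClimateZone
from .models import ModelFamily, SeriesPredictor, Trigger

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import FitResult, ParameterBounds, SAConfig

__all__ = [
    "rmse",
    "nse",
    "aicc",
    "pearson_significance",
    "CrossValidationResult",
    "loocv",
    "SeriesDataset",
    "ComparisonTable",
    "compare_models",
    "zone_frequency_summary",
    "trigger_bin_summary",
]


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if o.shape != f.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and of equal length")
    return o, f


def rmse(observed, predicted) -> float:
    o, f = _paired(observed, predicted)
    if o.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((o - f) ** 2)))


def nse(observed, predicted) -> float:
    """Nash-Sutcliffe efficiency; -inf flags an undefined value (the
    observed series has zero variance, so the null model is exact)."""
    o, f = _paired(observed, predicted)
    if o.size < 2:
        raise ValueError("need at least two observations")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0.0:
        return -math.inf
    return 1.0 - float(np.sum((o - f) ** 2)) / denom


def aicc(observed, predicted, k: int) -> float:
    """Small-sample corrected AIC; requires n > k + 2."""
    o, f = _paired(observed, predicted)
    n = o.size
    if n <= k + 2:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 2)")
    sse = float(np.sum((o - f) ** 2))
    sse = max(sse, 1e-300)  # a perfect fit would otherwise take log(0)
    return n * math.log(sse / n) + 2.0 * n * (k + 1) / (n - k - 2)


def pearson_significance(observed, predicted) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value; (nan, nan) when either
    series has zero variance."""
    o, f = _paired(observed, predicted)
    if o.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(o) == 0.0 or np.ptp(f) == 0.0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(o, f)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationResult:
    """Held-out predictions and validation RMSE from leave-one-out folds."""

    vrmse: float
    per_year_predictions: dict[int, float | None]
    n_folds: int

    def to_dict(self) -> dict:
        return {
            "vrmse": self.vrmse,
            "n_folds": self.n_folds,
            "per_year_predictions": {str(y): p for y, p in self.per_year_predictions.items()},
        }


def loocv(
    family: ModelFamily,
    trigger: Trigger | None,
    observations: PhenologyObservationSeries,
    temps: DailyTemperatureSeries,
    latitude: float,
    bounds: "ParameterBounds | None" = None,
    config: "SAConfig | None" = None,
    min_fold_years: int = 10,
) -> CrossValidationResult:
    """Leave-one-out cross-validation of one model on one series.

    Each year is withheld exactly once; the model is refitted on the
    remaining years (fold seed = base seed + fold index) and the fitted
    parameters predict the withheld year.  Requires at least
    ``min_fold_years + 1`` observations so every calibration fold keeps
    ``min_fold_years`` years.
    """
    from .calibration import (
        NONOCCURRENCE_PENALTY_DAYS,
        ParameterBounds,
        SAConfig,
        fit_model,
    )

    bounds = bounds if bounds is not None else ParameterBounds()
    config = config if config is not None else SAConfig()
    years = [int(y) for y in observations.years]
    if len(years) < min_fold_years + 1:
        raise ValueError(
            f"leave-one-out needs >= {min_fold_years + 1} years; series has {len(years)}"
        )
    held_out: dict[int, float | None] = {}
    for fold, year in enumerate(years):
        train = observations.replace_observations(
            {y: d for y, d in observations.observations.items() if y != year}
        )
        fit = fit_model(
            family,
            trigger,
            train,
            temps,
            latitude,
            bounds=bounds,
            config=config.with_seed(config.rng_seed + fold),
        )
        pred = SeriesPredictor(temps, latitude, [year]).predict(fit.params)[0]
        held_out[year] = None if np.isnan(pred) else float(pred)
    observed = observations.doys
    predicted = np.array(
        [math.nan if held_out[y] is None else held_out[y] for y in years]
    )
    resid = np.where(
        np.isnan(predicted), NONOCCURRENCE_PENALTY_DAYS, observed - predicted
    )
    return CrossValidationResult(
        vrmse=float(np.sqrt(np.mean(resid**2))),
        per_year_predictions=held_out,
        n_folds=len(years),
    )


# ---------------------------------------------------------------------------
# Cross-model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesDataset:
    """One fitting unit: a cleaned series plus its station's forcing data."""

    observations: PhenologyObservationSeries
    temps: DailyTemperatureSeries
    latitude: float
    climate_zone: ClimateZone = ClimateZone.OTHER


@dataclass
class ComparisonTable:
    """Aggregate accuracy of the two-trigger model and the comparison
    models over a collection of series (one row per model family)."""

    table: pd.DataFrame
    per_series: list[dict[str, "FitResult"]] = field(default_factory=list)

    COLUMNS = (
        "model",
        "mean_rmse",
        "mean_nse",
        "mean_pearson_r",
        "pct_significant",
        "mean_aicc",
        "mean_vrmse",
    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def compare_models(
    datasets: "Sequence[SeriesDataset] | SeriesDataset",
    bounds: "ParameterBounds | None" = None,
    config: "SAConfig | None" = None,
    include_loocv: bool = False,
    loocv_config: "SAConfig | None" = None,
    significance_level: float = 0.05,
) -> ComparisonTable:
    """Fit all four model families to every series and tabulate mean
    metrics per family (validation RMSE only when ``include_loocv``).

    The two-trigger model row reports its selected optimum (lower-RMSE
    trigger) per series.  Per-series, per-family seeds are derived from
    the base seed so reruns are exactly reproducible.
    """
    from .calibration import ParameterBounds, SAConfig, fit_model, select_optimum_tpforc

    bounds = bounds if bounds is not None else ParameterBounds()
    config = config if config is not None else SAConfig()
    if isinstance(datasets, SeriesDataset):
        datasets = [datasets]
    jobs: list[tuple[str, ModelFamily, Trigger | None]] = [
        ("tpforc_t", ModelFamily.TPFORC, Trigger.TEMPERATURE),
        ("tpforc_p", ModelFamily.TPFORC, Trigger.PHOTOPERIOD),
        ("uniforc", ModelFamily.UNIFORC, None),
        ("photothermal", ModelFamily.PHOTOTHERMAL, None),
        ("m1", ModelFamily.M1, None),
    ]
    per_series: list[dict[str, "FitResult"]] = []
    for i, ds in enumerate(datasets):
        fits: dict[str, "FitResult"] = {}
        for j, (label, family, trigger) in enumerate(jobs):
            fits[label] = fit_model(
                family,
                trigger,
                ds.observations,
                ds.temps,
                ds.latitude,
                bounds=bounds,
                config=config.with_seed(config.rng_seed + 101 * i + j),
            )
        fits["tpforc"], _ = select_optimum_tpforc(fits["tpforc_t"], fits["tpforc_p"])
        per_series.append(fits)

    rows = []
    row_models = ("tpforc", "uniforc", "photothermal", "m1")
    for label in row_models:
        fits = [s[label] for s in per_series]
        vrmse = math.nan
        if include_loocv:
            cv_cfg = loocv_config if loocv_config is not None else config
            vrmses = []
            for i, (ds, s) in enumerate(zip(datasets, per_series)):
                fit = s[label]
                cv = loocv(
                    fit.family,
                    fit.trigger,
                    ds.observations,
                    ds.temps,
                    ds.latitude,
                    bounds=bounds,
                    config=cv_cfg.with_seed(cv_cfg.rng_seed + 1009 * i),
                )
                vrmses.append(cv.vrmse)
            vrmse = float(np.mean(vrmses))
        finite_nse = [f.nse for f in fits if math.isfinite(f.nse)]
        rows.append(
            {
                "model": label,
                "mean_rmse": float(np.mean([f.rmse for f in fits])),
                "mean_nse": float(np.mean(finite_nse)) if finite_nse else math.nan,
                "mean_pearson_r": float(np.nanmean([f.pearson_r for f in fits])),
                "pct_significant": 100.0
                * float(np.mean([f.pearson_p < significance_level for f in fits])),
                "mean_aicc": float(np.mean([f.aicc for f in fits])),
                "mean_vrmse": vrmse,
            }
        )
    return ComparisonTable(pd.DataFrame(rows, columns=list(ComparisonTable.COLUMNS)), per_series)


# ---------------------------------------------------------------------------
# Trigger-frequency summaries
# ---------------------------------------------------------------------------


def zone_frequency_summary(
    records: Iterable[Mapping],
    by_species: bool = False,
    small_sample_n: int = 5,
) -> pd.DataFrame:
    """Share of photoperiod- vs temperature-triggered optimum models per
    climate zone (and phenophase; optionally species).

    ``records`` are mappings with keys ``zone``, ``phenophase``,
    ``trigger`` and optionally ``species``.  Zones with no series are
    omitted; cells with ``n <= small_sample_n`` are flagged.  Within each
    cell the two percentages sum to 100.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        return pd.DataFrame(
            columns=["zone", "phenophase", "pct_photoperiod", "pct_temperature", "n", "small_sample"]
        )
    df["zone"] = df["zone"].map(lambda z: ClimateZone(z).value)
    df["trigger"] = df["trigger"].map(lambda t: Trigger(t).value)
    keys = ["zone", "phenophase"] + (["species"] if by_species else [])
    rows = []
    for key_vals, grp in df.groupby(keys, sort=False):
        n = len(grp)
        pct_p = 100.0 * float(np.mean(grp["trigger"] == Trigger.PHOTOPERIOD.value))
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update(
            pct_photoperiod=pct_p,
            pct_temperature=100.0 - pct_p,
            n=n,
            small_sample=n <= small_sample_n,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {z.value: i for i, z in enumerate(ZONE_ORDER)}
    out = out.sort_values(
        keys, key=lambda col: col.map(order) if col.name == "zone" else col
    ).reset_index(drop=True)
    return out


def trigger_bin_summary(
    records: Iterable[Mapping],
    covariate: str,
    bin_width: float,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Proportion of trigger types per covariate bin, e.g. 10-day bins of
    winter duration or 0.1 degC bins of spring temperature variability;
    bins holding fewer than ``min_sites`` records are excluded."""
    df = pd.DataFrame(list(records))
    if df.empty or covariate not in df.columns:
        return pd.DataFrame(
            columns=["bin_left", "bin_right", "pct_photoperiod", "pct_temperature", "n"]
        )
    df["trigger"] = df["trigger"].map(lambda t: Trigger(t).value)
    left = np.floor(df[covariate].to_numpy(float) / bin_width) * bin_width
    df = df.assign(_bin=np.round(left, 10))
    rows = []
    for b, grp in df.groupby("_bin", sort=True):
        if len(grp) < min_sites:
            continue
        pct_p = 100.0 * float(np.mean(grp["trigger"] == Trigger.PHOTOPERIOD.value))
        rows.append(
            {
                "bin_left": float(b),
                "bin_right": float(b) + bin_width,
                "pct_photoperiod": pct_p,
                "pct_temperature": 100.0 - pct_p,
                "n": len(grp),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "pct_photoperiod", "pct_temperature", "n"]
    )
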
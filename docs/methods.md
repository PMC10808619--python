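# Methods

This note documents the models, numerical choices and synthetic-data
design behind `tpforc`, and what the test suite does and does not
establish.

## Forward models

**Two-trigger forcing model.**  A phenology year `y` is driven by daily
mean air temperature from 1 December of `y−1` through 31 December of
`y`.  Bud growth starts on `D_start`, the first day the trigger fires:

* temperature trigger: first day with `T > T_start`, searched strictly
  after 20 January (the climatological coldest date), i.e. from
  21 January;
* photoperiod trigger: first day with daylength `> P_start`, searched
  strictly after the previous winter solstice (pinned to day-of-year
  355; the ±1-day astronomical drift of the true solstice is far below
  model sensitivity).

Threshold comparisons are strict (`>`), and accumulation includes
`D_start` itself.  The daily rate is the decreasing-logistic sigmoid
`R_f(T) = 1/(1+exp(f_a(T−f_b)))` with `f_a < 0` (so the rate increases
with temperature) and `f_b > 0` (the midpoint temperature, where
`R_f = 0.5`).  The event is the first day the running sum reaches `F*`.
If the trigger never fires, or `F*` is unmet by 31 December,
the year is a *non-occurrence* — a first-class value (`None`/NaN), not
an exception.

**Comparison models** accumulate from the fixed anchor 1 January:

| family       | daily rate                          | free parameters |
|--------------|-------------------------------------|-----------------|
| uniforc      | `sigmoid(T)`                        | `f_a, f_b, F*` (3) |
| photothermal | `(daylength/24) · sigmoid(T)`       | `f_a, f_b, F*` (3) |
| m1           | `(daylength/10) · max(T − T_base, 0)` | `T_base, F*` (2) |

These follow the canonical literature formulations; the anchor is fixed
at 1 January rather than fitted.  The parameter counts are the `k`
entering AICc (two-trigger model: 4).

**Daylength** uses the Forsythe et al. (1995) revision of Schoolfield's
equations: solar declination from the revolution angle, daylength from
the sunset hour-angle arccosine with coefficient `p` (degrees below the
horizon defining day).  Default `p = 0.8333°` (sunrise/sunset including
refraction and the solar half-disc); the arccos argument is clamped to
[−1, 1] so polar day/night return 24 h/0 h.  This default reproduces the
11.0 h–13.2 h annual daylength range at 18.2°N, the southern end of the
kind of monsoon transect the package targets.

**Calendars.**  All date arithmetic uses real calendar dates; leap years
are handled by the calendar, and predictions are reported as day-of-year
of the phenology year (a December event of the preceding year maps to
DOY ≤ 0 on the continuous axis — it can arise for unphysical parameter
vectors during optimisation and is scored like any other residual).

## Data screening

Phenology series are screened the way national phenology network series
are typically cleaned: a single-pass removal of observations more than
two sample standard deviations (n−1 denominator) from the series mean —
statistics computed once on the full series, so re-applying the screen
with the original statistics is a no-op — followed by rejection of
series shorter than 10 years.  Screening order is outliers first, then
the length filter.  Temperature series must be gapless; as a convenience
for imperfect archives, gaps of ≤ 3 days may be linearly interpolated
(opt-in), longer gaps are data errors.

## Calibration

Each series is fitted independently by minimising the RMSE between
observed and predicted dates.  Years the model fails to predict
contribute a fixed 100-day penalty residual, keeping the objective
finite and strongly disfavouring parameter vectors that lose years.

The optimiser is Metropolis simulated annealing over a box:

* bounds (defaults): `T_start ∈ [−5, 25] °C`, `P_start ∈ [6, 20] h`,
  `f_a ∈ [−2, −0.01]`, `f_b ∈ [0.1, 30] °C`, `F* ∈ [1, 200]`,
  `T_base ∈ [−5, 15] °C` — generous physiological ranges for
  mid-latitude deciduous trees;
* Gaussian proposals with SD = 0.1 × bound width per coordinate,
  reflected at the bounds;
* acceptance of uphill moves with probability `exp(−Δ/temperature)`;
  initial temperature 10 d, geometric cooling ×0.9 per stage;
* default schedule 5 restarts × 60 stages × 200 iterations; restarts are
  *screened*: 200 uniform scan points are ranked first and the restart
  chains start from the best of them, which locates narrow basins far
  more reliably than blind restarts;
* after annealing, a deterministic compass (coordinate) search polishes
  the best point, with per-coordinate steps shrinking from 5% to 0.1% of
  the bound width.  The RMSE surface is piecewise constant (predictions
  are whole days), and a cooled annealer routinely stops 0.2–0.4 d above
  the attainable plateau; the polish removes that optimizer noise, which
  otherwise contaminates sub-model selection.

Everything is driven by a single integer seed; identical seeds give
bit-identical fits.  Two reduced presets, `small_budget` (2 × 30 × 60)
and `medium_budget` (3 × 40 × 100), are provided for cross-validation
folds and simulation studies; the test suite uses them so the full suite
runs in minutes.

**Sub-model selection.**  Both triggers are fitted and the lower-RMSE
fit is the local optimum; an exact tie goes to the photoperiod variant
(an arbitrary but fixed rule).

**Identifiability caveat.**  `f_a`, `f_b` and `F*` trade off strongly;
recovery claims are made on predicted dates, not raw parameter values.
More fundamentally, when the growth rate around the trigger date is
negligible (midpoint far above late-winter temperatures), either trigger
degenerates to a fixed calendar start date and the two sub-models become
observationally equivalent — trigger identification is then meaningless
regardless of optimiser effort.  Trigger labels are informative exactly
in the regime where pre-spring growth is non-negligible.

## Evaluation

* RMSE (days); NSE `= 1 − SSE/SS_mean` (−∞ sentinel reported as
  "undefined" when the observed series has zero variance); AICc
  `= n ln(SSE/n) + 2n(k+1)/(n−k−2)`, undefined for `n ≤ k+2` (and SSE is
  floored at 1e−300 so a numerically perfect fit does not take log 0);
  Pearson r with two-sided p (scipy), significance threshold 0.05.
* Leave-one-out cross-validation refits the model n times, each fold
  excluding one year (fold seed = base seed + fold index, so folds are
  independent and reproducible) and predicting it from the rest; VRMSE
  is the RMSE of the held-out predictions.  Folds are fitted from
  scratch, not warm-started from the full fit.
* The model-comparison table reports per-family means of RMSE, NSE, r,
  % significant, AICc and (optionally) VRMSE over a collection of
  series, with the two-trigger row showing the selected optimum per
  series.
* Zone summaries report the share of photoperiod- vs temperature-labelled
  optima per climate zone (north→south order), flagging cells with
  n ≤ 5; climate-bin summaries report trigger shares per 10-day winter
  duration bin and per 0.1 °C spring-variability bin, dropping bins with
  fewer than 5 sites.

## Climate covariates

For each series, with the mean phenological date `D̄` (rounded multiyear
mean day of year): winter temperature = mean over 1 Dec (prev.) – end of
February; winter duration = mean count of days below 5 °C from 1 Nov
(prev.) to `D̄`; spring temperature variability = mean over years of the
sample SD of residuals from a within-window linear detrend of the 60
days ending the day before `D̄`.  (Whether detrending should be
within-window per year or across years per calendar day is a genuinely
open choice; within-window is implemented.)

## Synthetic data

The generator replaces non-redistributable network observations:

* **Weather**: `T(d) = mean − amplitude·cos(2π(doy − phase + 182.5)/365.25)`
  plus stationary AR(1) noise (`noise_sd` is the marginal SD; innovation
  SD is `noise_sd·√(1−ρ²)`).  Defaults — mean 10 °C, amplitude 15 °C,
  peak at day 205, ρ = 0.7, SD 2.5 °C, 34 years (a 1981–2014 span) —
  emulate a lowland mid-latitude monsoon-climate station.
* **Phenology**: the chosen truth is run forward per year; rounded
  Gaussian observation noise (default SD 1 d) is added, optionally
  snapped to the every-other-day visiting grid of professional
  observation programmes; non-occurring years are dropped, as a field
  observer records only events that happen.
* **Truths**: default thresholds 12 h / 5 °C, slope −0.4, `F* = 15`.
  The sigmoid midpoint is deliberately placed near trigger-time
  temperatures (5 °C for the mid-latitude default; for networks, the
  station's climatological day-60–120 mean, floored at 5 °C) — the
  regime where the trigger leaves a detectable signature (see the
  identifiability caveat above).  Under these defaults a 40°N station
  leafs out around day 105–125 with interannual SD ≈ 4 d.
* **Networks**: stations evenly spaced over 18.2–50°N; annual mean
  falling 0.7 °C per degree from 24 °C at the southern end while the
  seasonal amplitude grows 0.3 °C per degree from 8 °C — the broad
  monsoon-transect pattern (equable south, continental north).  The
  generating trigger is photoperiod south of 34°N and temperature north
  of it, creating a recoverable zone gradient.  Climate zones are
  assigned by latitude band.

What the generator does **not** emulate: precipitation/humidity
controls, frost damage, spatial correlation between stations, trends or
regime shifts in the climate, chilling (endodormancy) dynamics, or
species mixtures at a station.  Passing recovery tests therefore show
that the estimation machinery works when the model class is correct and
weather statistics are stationary — not that the two-trigger model is
true of any real forest.

## Problem sizes used by the test suite

The suite runs the full scientific checks at deliberately compact sizes:
trigger/date recovery uses 20 replicates per trigger of 30-year series
at 40°N with the `small_budget` annealer; cross-validation checks use
12-year series; the transect study fits 20 stations × 2 sub-models with
the `medium_budget` annealer.  These sizes are the package's chosen
defaults for its own regression studies; the machinery scales to larger
schedules by raising the `SAConfig` counts.

## Known limitations

* Single-series calibration only; no joint (hierarchical) fitting across
  stations or species.
* No chilling sub-model: the two-trigger model is one-phase by design,
  and the comparison set contains only one-phase models.
* The annealer's screened multistart and compass polish reduce, but do
  not eliminate, optimizer noise; on series where the two triggers are
  near-equivalent, selection can flip between runs with different seeds.
* NSE and Pearson statistics assume interannually independent residuals;
  autocorrelated observation errors would make the reported p-values
  optimistic.
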
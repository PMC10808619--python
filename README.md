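# tpforc

Process-based spring phenology modelling with temperature- and
photoperiod-triggered bud growth initiation.

## The problem

The date on which deciduous trees unfold their first leaves or open
their first flowers is set by how winter buds leave dormancy.  Classic
one-phase "forcing" models accumulate a temperature-dependent bud growth
rate from a prescribed calendar date (1 January) until a critical amount
of forcing is reached.  They ignore *when* bud growth actually becomes
possible — which, depending on species and climate, is cued either by
rising temperature or by lengthening daylength.

`tpforc` implements a two-trigger forcing model.  Bud growth starts on
the day `D_start` when the trigger fires:

* **temperature trigger** — the first day after the climatological
  coldest date (20 January) with daily mean temperature above a
  threshold `T_start`;
* **photoperiod trigger** — the first day after the previous winter
  solstice with daylength above a threshold `P_start` (daylength from
  latitude and day of year by the revised-Schoolfield equations of
  Forsythe et al., coefficient p = 0.8333°).

From `D_start`, each day contributes a sigmoid growth rate

```
R_f(T) = 1 / (1 + exp(f_a (T − f_b))),      f_a < 0, f_b > 0
```

and the phenophase occurs on the first day `D_s` with

```
S_f = Σ_{t = D_start}^{D_s} R_f(T_t) ≥ F*.
```

Each sub-model (`TPForc_t`, `TPForc_p`) has four fitted parameters:
`T_start` or `P_start`, `f_a`, `f_b`, `F*`.  Parameters are calibrated
per station–species–phenophase series by Metropolis simulated annealing
minimising RMSE; the sub-model with the lower RMSE is the local optimum
and its trigger labels the series.  Three one-phase comparison models
(UniForc, Photothermal, M1) share the machinery, and fits are scored by
RMSE, Nash–Sutcliffe efficiency, small-sample AICc, Pearson correlation
and leave-one-out cross-validation (VRMSE).

Because multi-decade phenology network data are rarely redistributable,
the package includes a synthetic-data module (seasonal-sinusoid + AR(1)
daily weather; phenology generated by a known truth with observation
noise) so that calibration, trigger selection, cross-validation and
climate-zone summaries are fully testable offline.

Intended users: phenology and climate-impact researchers who fit
process-based spring phenology models to station observation series.

## Worked example

```python
from tpforc import SpringPhenologyModel, SAConfig
from tpforc.synthetic import (WeatherGenConfig, generate_temperature,
                              generate_phenology, default_truth)

cfg = WeatherGenConfig(rng_seed=42)            # 34 years of daily weather
temps = generate_temperature(cfg)
truth = default_truth(rng_seed=42)             # photoperiod-triggered, P_start = 12 h
obs, _ = generate_phenology(truth, temps, 40.0, cfg.years)

model = SpringPhenologyModel(obs, temps, latitude=40.0)
res = model.fit(config=SAConfig.medium_budget(rng_seed=1))
print(res.summary())
```

```
Spring Phenology Model Results
==============================================
Series:                 SYN001/synthetic_tree/first_leaf_unfolding
Model:                  tpforc_p
No. years:              34
No. parameters (k):     4
----------------------------------------------
f_a                          -0.2498
f_b                           7.6315
f_star                       10.8500
p_start                      11.9704
----------------------------------------------
RMSE (days)                   0.9235
NSE                           0.9208
AICc                          6.7347
Pearson r                     0.9597
Pearson p                  3.371e-19
----------------------------------------------
RMSE temperature sub-model          1.7150
RMSE photoperiod sub-model          0.9235
Selected trigger                photoperiod
==============================================
```

The fit identifies the generating cue: the photoperiod sub-model wins
(RMSE 0.92 d vs 1.72 d) and recovers the daylength threshold (11.97 h
fitted vs 12.0 h true).  The fitted series explains 92% of the
interannual variance (NSE 0.92); the individual sigmoid parameters trade
off against `F*` and need not match the generating values even when the
predicted dates do.

`res.crossval()` adds leave-one-out validation; `res.plot_fit()` draws
observed vs fitted dates (requires matplotlib).

## Command line

A thin CLI chains the pipeline on CSV files
(`stations.csv`, `temperatures.csv`, `phenology.csv`):

```
tpforc simulate  --seed 1 --out net/          # synthetic network + hidden truths
tpforc fit       --config run.yaml --seed 1 --out fits/
tpforc crossval  --config run.yaml --seed 1 --out cv/
tpforc compare   --config run.yaml --seed 1 --out cmp/   # 4 model families
tpforc summarize --config run.yaml --seed 1 --out sum/   # zone / climate-bin tables
```

All commands are deterministic given `--seed`; every output directory
carries a `run_info.json` with the seed and a config hash.

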
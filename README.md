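# cavemon

Design optimization for long-term monitoring of cave-dwelling fauna.

Monitoring programs around iron-cave landscapes census a fixed set of
target taxa in dozens of caves, in the dry and the rainy season, year
after year. Such programs are expensive and intrusive, and their design
raises four statistical questions that this package answers as a
reusable, tested pipeline:

1. **What structures community composition?** A partial redundancy
   analysis (RDA) of the Hellinger-transformed survey-event × taxon
   matrix on standardized environmental and landscape-disturbance
   predictors, conditioning out the highland a cave sits on, with
   marginal permutation tests per term and an Ezekiel-adjusted R².
2. **Does the season change the temporal trend?** Per cave × taxon, an
   OLS fit of `count ~ date + season + date:season` (≥5 surveys per
   season required), with Benjamini–Hochberg adjustment of the
   interaction p-values across all models. No significant interactions
   means trends can be monitored in a single season.
3. **How many surveys are enough?** For each cave × taxon × season, the
   full-data trend slope is compared with slopes refit on random
   k-survey subsets (10 draws without replacement per k, k = 2…K); the
   RMSE-vs-k curve's stabilization point and a dry-vs-rainy comparison
   give a per-taxon effort recommendation.
4. **Which taxa indicate disturbance?** Two tracks: per-species negative
   binomial GLMs of abundance on season-nested-in-year, distance to
   mine and mining cover, with PIT-trap resampling inference and free
   step-down family-wise adjustment; and second-stage regressions of
   per-cave trend slopes (≥3-year span, ≥10 caves) on each disturbance
   metric, tested by likelihood ratio. Taxa significant in both tracks
   with coherent disturbance directions are candidate indicators.

A synthetic-data generator (`cavemon.simulate`) produces monitoring
datasets with the assumed structure — negative-binomial counts with
cave random intercepts, seasonal offsets, per-cave×taxon trends, and
disturbance effects on level and/or trend — with full ground truth, so
every stage is validated by parameter recovery and null calibration
rather than by fixture files. See `docs/methods.md` for the models,
defaults, and design decisions.

## Worked example

Simulate a 20-cave × 6-taxon, 4-year program and run every stage:

```python
from cavemon import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    out_dir="demo", seed=42,
    simulation=dict(n_caves=20, n_taxa=6, n_years=4),
    n_perm=199, n_resample=199,
))
```

which writes per-stage CSVs (`rda.csv`, `interactions.csv`,
`effort_curves.csv`, `abundance_effects.csv`, …) plus `summary.json`:

```json
{
  "rda":         {"adjusted_r2": 0.1237, "unexplained_fraction": 0.8247,
                  "significant_terms": 3},
  "seasonality": {"n_models": 90, "n_significant": 0},
  "effort":      {"n_curves": 240, "median_recommended_k": 4.0,
                  "season_recommendations": {"dry": 3, "rainy": 3}},
  "indicators":  {"abundance_track_species": 0, "trend_track_species": 0,
                  "consistent_indicators": 0}
}
```

Reading it: the measured gradients explain ~18% of community
composition (adjusted R² 0.12) — most variance is unexplained, as is
typical for these communities; none of the 90 eligible cave × taxon
units shows a season-dependent trend after FDR control, so a
single-season design would not hurt trend detection; RMSE curves
stabilize around 4 surveys with no season preference at this simulation's
symmetric noise; and under the generator's default modest effect sizes
no taxon clears both indicator tracks at this small problem size.

The same stages are available from the shell:

```bash
cavemon simulate --seed 42 --out-dir demo
cavemon rda --surveys demo/surveys.csv --covariates demo/covariates.csv \
            --nperm 999 --seed 1 --out rda.csv
cavemon run-all --seed 42 --out-dir demo
```

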
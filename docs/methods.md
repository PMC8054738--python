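# Methods

`cavemon` reimplements, as a tested pipeline, the statistical workflow
used to optimize long-term monitoring of cave invertebrate communities
around iron-mining landscapes: which environmental and disturbance
gradients structure community composition, whether trend detection
depends on the sampling season, how many surveys per season suffice to
pin down a temporal abundance trend, and which taxa respond to
disturbance consistently enough to serve as indicator species. This
note records the models, the default parameter choices, and the design
decisions taken where the workflow left genuine freedom.

## Data model

The unit of observation is one abundance count of one target taxon in
one cave on one survey date, labelled with a season (`dry`/`rainy`).
Counts are absolute censuses (every individual found is counted), and
because every target taxon is actively searched on every survey, zeros
are true absences, never missing data. Dates are carried both as
calendar dates and as decimal years since the first survey in the
dataset (`t`), so trend slopes read as individuals per year; any affine
date encoding gives identical test statistics.

Duplicate (cave, taxon, date) rows are resolved by keeping the maximum
count — the conservative census reading that the larger of two
simultaneous counts is the better lower bound on abundance — and the
resolution is logged. Repeat surveys within one season and year are kept
as separate observations.

Two inclusion filters recur downstream: the seasonality screen requires
at least five distinct survey dates in *each* season per cave × taxon
(guarding against overfitting a four-parameter interaction model), and
the trend analyses require surveys spanning at least three distinct
calendar years (repeat surveys within a year do not extend the span).
Both filters are idempotent and monotone in their thresholds.

## Synthetic data generator

The generator emulates the monitoring design the analyses assume: by
default 95 caves × 33 taxa over 4 years starting in 2015, each cave
surveyed once or twice per season per year, with dry-season surveys in
mid-year and rainy-season surveys near the start of the year (dates
jittered uniformly within each window). Counts are negative binomial on
the log link:

    count ~ NB(mean = exp(a_taxon + u_cave + b_season·I(dry)
                          + slope_{cave,taxon}·t
                          + b_mine·mining + b_dist·(log dist − log 800)),
               size = theta_taxon)

with `slope_{cave,taxon} = trend_taxon + cave jitter +
g_mine·mining + g_dist·(log dist − log 800)`. Separating the level
effects (`b_*`) from the trend effects (`g_*`) gives each indicator
track its own recoverable ground truth. Default hyper-parameters
(baseline log-abundance N(1.3, 0.8); cave intercept SD 0.7; seasonal
offset SD 0.4; taxon trend SD 0.10/yr with 0.05 cave jitter; level
disturbance SDs 0.6 and 0.3; trend disturbance SDs 0.06 and 0.03;
theta = 2) were chosen once to give realistic small counts (median in
the low single digits to tens), strong between-cave heterogeneity, and
overdispersion typical of invertebrate census data. Covariates: mining
cover is zero for roughly half the caves and Beta-distributed otherwise,
creeping upward over the years for mined caves; distance to mine is
log-normal and lower for mined landscapes; two buffer scales (500 m,
1000 m) are correlated versions of the same signal.

The generator intentionally produces NB counts even though the trend
screens fit Gaussian OLS on raw counts — that mismatch is the realistic
situation those screens face, and the calibration tests measure the
screens under it, not under a sanitized Gaussian world. What the
generator does *not* emulate: spatial autocorrelation between caves,
within-cave micro-habitat structure, observer effects, or detection
failure. Passing tests therefore certify the statistical machinery under
clustered overdispersed counts, not robustness to those further
features of real data.

`simulate_null_dataset` zeroes every trend and disturbance effect
(seasonal *level* offsets are retained — they do not move slopes), and
is the harness for all type-I-error tests. Output is a pure function of
the config including its seed.

## Community ordination

The survey-event × taxon count matrix is Hellinger-transformed
(square root of row-relative abundances; all-zero rows stay zero and
are flagged), continuous predictors are standardized (mean 0, SD 1,
n−1 denominator), and a partial redundancy analysis is fitted with the
highland (the massif a cave sits on) as conditioning variable. Inertia
is partitioned as conditional + constrained + residual, verified to the
total to 1e−8. Each term's marginal contribution is Type-III-like:
constrained inertia of the full model minus that of the model without
the term, with

    F = (SS_term / df_term) / (SS_resid / df_resid),
    df_resid = n − 1 − df_conditioning − df_constrained.

Significance comes from reduced-model residual permutation: residuals
of the model without the tested term are permuted, added back to the
reduced fit, and F recomputed; p = (1 + #{F* ≥ F}) / (1 + n_perm), so
the smallest attainable p is 1/(n_perm + 1). An exhaustive mode
enumerates all n! permutations on tiny instances and is used as the
exactness oracle in the tests. The adjusted R² is the Ezekiel
adjustment applied to the semi-partial R² (constrained over
post-conditioning inertia), with n reduced by the conditioning df.

"Season nested in year" has two codings, both exposed: `contrast`
(one dry-vs-rainy column, 1 df, matching ordination tables that print a
single row for the term) and `nested` (year dummies plus a per-year
season contrast, tested jointly with its full df — the default). The
two answer slightly different questions; results tables report the df
actually used. The buffer scale for land covers (500 vs 1000 m) is a
switch, defaulting to 1000 m, with covariates matched to the survey
year.

## Seasonality screen

Per eligible cave × taxon (≥5 surveys in each season, ≥2 distinct dates
per season), OLS of `count ~ t + season + t:season`; the two-sided
t-test p-value of the interaction coefficient (difference in slope,
individuals/yr, dry vs rainy) is the unit result. Benjamini–Hochberg
adjustment is applied **jointly across all fitted models** — the screen
answers a single program-level question, so one family is the natural
choice; a per-taxon family is available but off by default. The screen's
decision contract is exactly the count of adjusted p < alpha: zero means
trend detection is season-agnostic and a monitoring program can
concentrate on one season.

Fitting Gaussian OLS to raw counts is deliberate fidelity to the
workflow being reproduced; the type-I calibration test shows the
interaction t-test holds its nominal level within the 99% binomial band
under the generator's NB world (the interaction contrast is robust to
the count-variance structure at these sample sizes). All-zero units
yield an exact zero fit; the interaction then carries no evidence and
is reported with p = 1 rather than NaN.

## Effort subsampling

Per cave × taxon × season with ≥3 surveys: the full-data OLS slope is
the reference; for each k from 2 to K (all surveys available), `n_draws`
(default 10, as in the reproduced design) subsets of k surveys are drawn
without replacement, the slope refit, and

    rmse(k) = sqrt(mean over draws of (slope_subset − slope_full)²)

recorded. Draws with all surveys on one date cannot yield a slope and
are redrawn (up to 100 attempts, then dropped with a log entry). Only
the date slope is compared by default — the temporal trend is the
estimand and the intercept is nuisance — but a switch includes the
intercept in a two-component deviation.

The stabilization point is the smallest k after which successive rmse
changes stay within `rel_tol` (default 0.1) times rmse(2); a flat-zero
curve stabilizes at 2. This operationalizes the visual "curve has
flattened" judgement; `rel_tol` is exposed. Per taxon, curves are
averaged over caves within season, the recommended season is the one
with the lower mean rmse integrated (trapezoid) over the shared k-range
(exact tie → "both"), and the recommended k is the median stabilization
point (ceiling).

## Indicator screen

**Abundance track.** Per species, an NB GLM of counts per survey event
on season-nested-in-year (year dummies + per-year season contrast),
standardized log distance to mine, and standardized mining cover. Each
term is tested by the likelihood-ratio statistic against the model
without it. Inference is resampling-based: probability-integral-
transform (PIT) residuals are computed under the reduced model
(randomized PIT for discrete counts), resampled, mapped back through
the inverse PIT at the reduced-model fitted values, and the models
refit; p = (1 + #{LR* ≥ LR}) / (1 + n_resample), default 999
iterations. Family-wise adjustment across species uses free step-down
maxT over the joint resamples, which requires — and gets — the same
resample indices for every species within an iteration.

Two implementation choices matter here. First, residuals are resampled
in **cave blocks** (each original cave is assigned a donor cave drawn
with replacement; rows are matched positionally, recycling if the donor
has fewer surveys). Surveys of one cave share unmodelled cave-level
variation, and both disturbance metrics are cave-level covariates; an
iid row bootstrap understates their null variance so badly that the
nominal 5% test rejected ~46% of true nulls in calibration runs, while
cave-block resampling restores the nominal level. The iid bootstrap
remains available as `resample_unit="row"`. Second, dispersions are
pinned at their observed estimates during resampling refits, making
each refit a pure IRLS solve; the test statistic is defined with those
plug-in dispersions consistently for observed and resampled data.

**Trend track.** Per-cave trend slopes (OLS, year-span filter) are the
response in a second stage: for each taxon with ≥10 cave slopes, a
single-predictor regression of slope on each disturbance-metric variant
(log distance; mining cover at each buffer scale and covariate year),
tested by likelihood-ratio against the intercept-only model. All
variants are reported; for classification each metric is represented by
its best-fitting variant (highest log-likelihood).

**Classification.** Direction labels (positive / negative / –) are
assigned per metric per track at alpha = 0.05. A taxon is a candidate
indicator when it has at least one significant effect in each track and
all implied disturbance directions agree, with distance-to-mine effects
counted sign-reversed relative to mining-cover effects (farther from
the mine = less disturbed). The effort stage's recommended sampling
season is attached to the report when available.

## Numerical choices

* OLS: `lstsq`-based, Gaussian **ML** log-likelihood (variance RSS/n,
  not REML) so likelihood-ratio statistics of nested fits are valid;
  rank-deficient designs raise naming the collinear columns; exact fits
  report p = 1 for zero coefficients and p = 0 for nonzero ones.
* NB GLM: alternating IRLS for the coefficients and bounded 1-D ML for
  theta on the log scale, outer relative tolerance 1e−8, at most 100
  outer iterations, convergence honestly flagged; theta capped at 1e6
  (numerically the Poisson limit) and floored at 1e−4. Standard errors
  from the Fisher information at fixed theta. Cross-checked in the
  tests against statsmodels and a brute-force grid search.
* Likelihood-ratio tests use the upper chi-square tail; deviances
  negative only through numerical noise are clamped to zero, genuinely
  negative ones raise.
* Permutation and resampling p-values always use the add-one rule.
* Every stochastic stage takes a seed; the pipeline derives per-stage
  seeds from one top-level seed via `SeedSequence.spawn`, so stages can
  be rerun in isolation and reproduce byte-identical outputs.

## Problem sizes

The bundled validation work runs at a scaled version of the full
monitoring design: calibration datasets of 40–50 caves × 10–12 taxa ×
4 years with 1–2 surveys per season per year (≈500–650 survey events,
≈500 screen units), 99–199 permutations/resamples inside tests, and the
full 999 iterations in the end-to-end summary script. These sizes were
chosen as the smallest at which the binomial and Kolmogorov–Smirnov
calibration bands are informative; the estimators themselves carry no
size assumptions.

## Known limitations

* No mixed models: cave-level heterogeneity is handled by the generator
  and, for inference, by cave-block resampling — not by random-effect
  estimation.
* The NB GLM covers the single family the screen needs; no zero
  inflation, no spatial or phylogenetic correlation.
* The trend second stage tests metric variants one at a time without
  cross-variant multiplicity control, mirroring the reproduced
  workflow; the variant count is visible in the output for any reader
  wishing to discount it.
* Land-cover proportions and topographic distances are consumed as a
  table; no GIS computation is performed or planned.
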
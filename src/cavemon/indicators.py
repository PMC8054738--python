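"""Two-track screen for disturbance indicator taxa.

Track A (abundance level): per-species negative-binomial GLMs of counts
per survey event on season-nested-in-year, log distance to the nearest
mine and mining land cover. Inference is resampling-based: each term is
tested by a likelihood-ratio statistic against the model without it,
with the null distribution built by PIT-trap resampling (bootstrap of
probability-integral-transform residuals under the reduced model), and
family-wise adjustment across species by free step-down (maxT over the
joint resamples).

Track B (temporal trend): per-cave OLS trend slopes (caves spanning at
least three survey years), then single-predictor regressions of slope
on each disturbance metric variant (distance, mining cover per buffer
scale and year), tested by likelihood-ratio against an intercept-only
null; species with fewer than ten cave slopes are excluded.

A taxon is a candidate indicator when it shows at least one significant
effect in EACH track and the implied disturbance directions agree
(distance-to-mine effects count sign-reversed relative to mining-cover
effects: farther from the mine means less disturbed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from . import stats as cs
from .data import SurveyTable, filter_year_span, to_community_matrix

__all__ = [
    "IndicatorScreen",
    "fit_species_glms",
    "per_cave_trend_slopes",
    "trend_vs_disturbance",
    "classify_indicators",
]

DISTURBANCE_TERMS = ("dist_mine", "mining_cover")


# ---------------------------------------------------------------------------
# design assembly


def _season_year_dummies(meta: pd.DataFrame) -> tuple[np.ndarray, list]:
    years = sorted(meta["year"].unique())
    dry = (meta["season"] == "dry").to_numpy(dtype=float)
    cols, names = [], []
    for y in years[1:]:
        cols.append((meta["year"] == y).astype(float).to_numpy())
        names.append(f"year_{y}")
    for y in years:
        cols.append(dry * (meta["year"] == y).to_numpy())
        names.append(f"dry_in_{y}")
    return np.column_stack(cols), names


def _abundance_design(meta: pd.DataFrame, covariates: pd.DataFrame, buffer: int):
    cov = covariates.copy()
    years = np.sort(cov["year"].unique())
    match_year = np.clip(meta["year"].to_numpy(), years.min(), years.max())
    key = pd.DataFrame({"cave_id": meta["cave_id"], "year": match_year})
    merged = key.merge(cov, on=["cave_id", "year"], how="left", validate="many_to_one")
    if merged["dist_mine_m"].isna().any():
        missing = sorted(key.loc[merged["dist_mine_m"].isna(), "cave_id"].unique())
        raise ValueError(f"covariates missing for cave(s) {missing}")
    sy, sy_names = _season_year_dummies(meta)
    dist = cs.standardize(np.log(merged["dist_mine_m"].to_numpy()))
    mining = cs.standardize(merged[f"mining_{buffer}"].to_numpy())
    X = np.column_stack([np.ones(len(meta)), sy, dist, mining])
    term_cols = {
        "season_in_year": list(range(1, 1 + sy.shape[1])),
        "dist_mine": [1 + sy.shape[1]],
        "mining_cover": [2 + sy.shape[1]],
    }
    return X, term_cols


# ---------------------------------------------------------------------------
# PIT-trap resampling machinery


def _pit_residuals(y: np.ndarray, mu: np.ndarray, theta: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomized probability-integral-transform residuals for NB counts."""
    p = theta / (theta + mu)
    upper = sps.nbinom.cdf(y, theta, p)
    lower = sps.nbinom.cdf(y - 1, theta, p)
    u = lower + rng.random(y.size) * (upper - lower)
    return np.clip(u, 1e-10, 1 - 1e-10)


def _inverse_pit(u: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return sps.nbinom.ppf(u, theta, theta / (theta + mu))


def _lr_stat(y, X_full, X_red, theta_full, theta_red):
    """LR statistic with dispersions held fixed (resampling fast path)."""
    f = cs.nb_glm_fit(y, X_full, theta=theta_full)
    r = cs.nb_glm_fit(y, X_red, theta=theta_red)
    return max(0.0, 2.0 * (f.log_likelihood - r.log_likelihood))


def _stepdown_adjust(obs: np.ndarray, boot: np.ndarray) -> np.ndarray:
    """Free step-down (Westfall-Young maxT) adjusted p-values.

    ``obs``: (m,) observed statistics; ``boot``: (B, m) joint resampled
    statistics. Hypotheses are visited from largest to smallest observed
    statistic; the null reference for the j-th is the max statistic over
    the not-yet-rejected set, and monotonicity is enforced down the
    ordering.
    """
    m = obs.size
    order = np.argsort(-obs, kind="stable")
    B = boot.shape[0]
    adj = np.empty(m)
    # running max over the tail of the ordering, per resample
    tail_max = np.maximum.accumulate(boot[:, order[::-1]], axis=1)[:, ::-1]
    prev = 0.0
    for rank, j in enumerate(order):
        p = (1 + int((tail_max[:, rank] >= obs[j] - 1e-12).sum())) / (1 + B)
        prev = max(prev, p)
        adj[j] = prev
    return adj


def _cave_blocks(cave_ids: np.ndarray) -> list:
    """Row indices grouped by cave, each in survey order."""
    order = pd.Series(range(len(cave_ids))).groupby(cave_ids, sort=True)
    return [np.asarray(idx) for _, idx in order.groups.items()]


def _resample_indices(blocks: list, n: int, rng: np.random.Generator,
                      unit: str) -> np.ndarray:
    """One resample-index vector, shared across species.

    ``unit="cave"`` draws a donor cave (with replacement) for every
    original cave and assigns its residual rows positionally (recycled if
    the donor has fewer rows), preserving the within-cave correlation
    that cave-level covariates are tested against. ``unit="row"`` is the
    plain iid row bootstrap.
    """
    if unit == "row":
        return rng.integers(0, n, size=n)
    idx = np.empty(n, dtype=int)
    donors = rng.integers(0, len(blocks), size=len(blocks))
    for target, donor in zip(blocks, (blocks[d] for d in donors)):
        idx[target] = donor[np.arange(len(target)) % len(donor)]
    return idx


def fit_species_glms(
    matrix,
    covariates: pd.DataFrame,
    buffer: int = 1000,
    n_resample: int = 999,
    seed=None,
    resample_unit: str = "cave",
) -> pd.DataFrame:
    """Track A: per-species NB GLMs with PIT-trap resampling inference.

    Parameters
    ----------
    matrix : :class:`cavemon.data.CommunityMatrix` of counts per survey
        event (rows) and taxa (columns).
    covariates : per-cave (x year) covariate table.
    n_resample : PIT-trap iterations (999 reproduces the usual default).

    Returns a DataFrame with one row per species x term: coefficient
    (log link; NaN for the multi-column season term), Wald 95% CI,
    raw_p, adjusted_p (step-down across species within the term family)
    and a convergence flag. The same resample indices are used for every
    species within an iteration, which is what makes the step-down maxT
    adjustment valid.

    Residuals are resampled in cave blocks by default (see
    :func:`_resample_indices`): surveys of one cave share unmodelled
    cave-level variation, and the disturbance metrics are cave-level
    covariates, so an iid row bootstrap would understate their null
    variance. During resampling the dispersions are pinned at their
    observed estimates, so each refit is a pure IRLS solve.
    """
    X, term_cols = _abundance_design(matrix.meta, covariates, buffer)
    n = X.shape[0]
    taxa = matrix.taxa
    rng = np.random.default_rng(seed)
    blocks = _cave_blocks(matrix.meta["cave_id"].to_numpy())

    fits, kept, skipped = {}, [], []
    for s in taxa:
        y = matrix.counts[s].to_numpy(dtype=float)
        if np.all(y == 0):
            skipped.append((s, "all-zero counts"))
            continue
        fit = cs.nb_glm_fit(y, X)
        fits[s] = fit
        kept.append(s)

    rows = []
    for term, cols in term_cols.items():
        keep_idx = [i for i in range(X.shape[1]) if i not in cols]
        X_red = X[:, keep_idx]
        df_t = len(cols)

        # observed LR statistics and reduced fits per species
        obs, red_fits = {}, {}
        for s in kept:
            y = matrix.counts[s].to_numpy(dtype=float)
            red = cs.nb_glm_fit(y, X_red)
            red_fits[s] = red
            obs[s] = max(0.0, 2.0 * (fits[s].log_likelihood - red.log_likelihood))

        family = [s for s in kept if fits[s].converged and red_fits[s].converged]
        pit = {
            s: _pit_residuals(
                matrix.counts[s].to_numpy(dtype=float),
                np.exp(np.clip(X_red @ red_fits[s].coefficients, -30, 30)),
                red_fits[s].theta, rng,
            )
            for s in family
        }
        boot = np.zeros((n_resample, len(family)))
        for b in range(n_resample):
            idx = _resample_indices(blocks, n, rng, resample_unit)
            for si, s in enumerate(family):
                red = red_fits[s]
                mu_red = np.exp(np.clip(X_red @ red.coefficients, -30, 30))
                y_star = _inverse_pit(pit[s][idx], mu_red, red.theta)
                try:
                    boot[b, si] = _lr_stat(y_star, X, X_red,
                                           fits[s].theta, red.theta)
                except (np.linalg.LinAlgError, ValueError):
                    boot[b, si] = 0.0
        obs_vec = np.array([obs[s] for s in family])
        raw = (1 + (boot >= obs_vec[None, :] - 1e-12).sum(axis=0)) / (1 + n_resample)
        adj = _stepdown_adjust(obs_vec, boot)

        for si, s in enumerate(family):
            coef = se = np.nan
            if df_t == 1:
                coef = float(fits[s].coefficients[cols[0]])
                se = float(fits[s].standard_errors[cols[0]])
            z = sps.norm.ppf(0.975)
            rows.append({
                "taxon_id": s, "term": term, "coefficient": coef,
                "ci_low": coef - z * se if df_t == 1 else np.nan,
                "ci_high": coef + z * se if df_t == 1 else np.nan,
                "lr_stat": float(obs_vec[si]),
                "raw_p": float(raw[si]), "adjusted_p": float(adj[si]),
                "converged": True,
            })
        for s in kept:
            if s not in family:
                rows.append({
                    "taxon_id": s, "term": term, "coefficient": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "lr_stat": np.nan,
                    "raw_p": np.nan, "adjusted_p": np.nan, "converged": False,
                })
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Track B: trend slopes vs disturbance


def per_cave_trend_slopes(table: SurveyTable, min_years: int = 3) -> pd.DataFrame:
    """OLS trend slope per (cave, taxon) whose surveys span >= min_years
    distinct calendar years. Positive slope = increasing abundance."""
    eligible = filter_year_span(table, min_years)
    rows = []
    for (cave, taxon), grp in eligible.df.groupby(
        ["cave_id", "taxon_id"], observed=True, sort=True
    ):
        t = grp["t"].to_numpy(dtype=float)
        y = grp["count"].to_numpy(dtype=float)
        if len(np.unique(t)) < 2 or len(t) < 3:
            continue
        fit = cs.ols_fit(y, np.column_stack([np.ones_like(t), t]))
        rows.append({"cave_id": cave, "taxon_id": taxon, "slope": fit.slope,
                     "n_surveys": len(t)})
    return pd.DataFrame(rows, columns=["cave_id", "taxon_id", "slope", "n_surveys"])


def _metric_variants(covariates: pd.DataFrame) -> list:
    """Every disturbance-metric variant: distance (scale/year invariant)
    plus mining cover at each buffer scale and covariate year."""
    variants = [("dist_mine", None, None)]
    years = sorted(covariates["year"].unique())
    for scale in (500, 1000):
        if f"mining_{scale}" in covariates.columns:
            for y in years:
                variants.append(("mining_cover", scale, int(y)))
    return variants


def _metric_values(covariates: pd.DataFrame, metric: str, scale, year) -> pd.Series:
    if metric == "dist_mine":
        per_cave = covariates.groupby("cave_id")["dist_mine_m"].first()
        return np.log(per_cave)
    sub = covariates[covariates["year"] == year]
    return sub.set_index("cave_id")[f"mining_{scale}"]


def trend_vs_disturbance(
    slopes: pd.DataFrame,
    covariates: pd.DataFrame,
    min_caves: int = 10,
) -> pd.DataFrame:
    """Track B second stage: regress per-cave trend slopes on each single
    disturbance-metric variant; LRT against an intercept-only null.

    Returns one row per taxon x metric variant with the slope-of-slopes
    coefficient, LRT p-value and cave count; taxa with fewer than
    ``min_caves`` cave slopes are skipped.
    """
    rows = []
    variants = _metric_variants(covariates)
    for taxon, grp in slopes.groupby("taxon_id", sort=True):
        if len(grp) < min_caves:
            continue
        y = grp["slope"].to_numpy(dtype=float)
        for metric, scale, year in variants:
            vals = _metric_values(covariates, metric, scale, year)
            x = grp["cave_id"].map(vals).to_numpy(dtype=float)
            if np.isnan(x).any() or np.unique(x).size < 2:
                continue
            X = np.column_stack([np.ones_like(x), cs.standardize(x)])
            full = cs.ols_fit(y, X)
            null = cs.ols_fit(y, np.ones((len(y), 1)))
            p = cs.lrt(full.log_likelihood, null.log_likelihood, 1)
            rows.append({
                "taxon_id": taxon, "metric": metric,
                "scale": scale, "cov_year": year,
                "coefficient": float(full.coefficients[1]),
                "lrt_p": p, "log_likelihood": full.log_likelihood,
                "n_caves": len(grp),
            })
    return pd.DataFrame(
        rows, columns=["taxon_id", "metric", "scale", "cov_year",
                       "coefficient", "lrt_p", "log_likelihood", "n_caves"]
    )


# ---------------------------------------------------------------------------
# classification


def _direction(coef: float) -> str:
    return "positive" if coef > 0 else "negative"


def _implied(term: str, coef: float) -> int:
    """Implied disturbance-response direction: +1 favored, -1 averse.

    Mining-cover effects carry their own sign; distance-to-mine effects
    are sign-reversed (abundance rising with distance = disturbance-averse).
    """
    s = 1 if coef > 0 else -1
    return -s if term == "dist_mine" else s


def classify_indicators(
    abundance_effects: pd.DataFrame,
    trend_effects: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine the two tracks into an indicator report.

    For the trend track, each metric is represented by its best-fitting
    variant (highest log-likelihood). A taxon is flagged consistent when
    it has >= 1 significant effect in each track and every implied
    disturbance direction agrees.
    """
    taxa = sorted(
        set(abundance_effects.get("taxon_id", pd.Series(dtype=object)))
        | set(trend_effects.get("taxon_id", pd.Series(dtype=object)))
    )
    best_trend = {}
    if len(trend_effects):
        for (taxon, metric), grp in trend_effects.groupby(["taxon_id", "metric"]):
            best_trend[(taxon, metric)] = grp.loc[grp["log_likelihood"].idxmax()]

    rows = []
    for taxon in taxa:
        labels, implied = {}, []
        sig_abund = sig_trend = False
        for term in DISTURBANCE_TERMS:
            sub = abundance_effects[
                (abundance_effects.get("taxon_id") == taxon)
                & (abundance_effects.get("term") == term)
            ] if len(abundance_effects) else abundance_effects
            lab = "-"
            if len(sub):
                r = sub.iloc[0]
                if np.isfinite(r.get("adjusted_p", np.nan)) and r["adjusted_p"] < alpha:
                    lab = _direction(r["coefficient"])
                    implied.append(_implied(term, r["coefficient"]))
                    sig_abund = True
            labels[f"abundance_{term}"] = lab
        for term in DISTURBANCE_TERMS:
            r = best_trend.get((taxon, term))
            lab = "-"
            if r is not None and r["lrt_p"] < alpha:
                lab = _direction(r["coefficient"])
                implied.append(_implied(term, r["coefficient"]))
                sig_trend = True
            labels[f"trend_{term}"] = lab
        consistent = sig_abund and sig_trend and len(set(implied)) == 1
        response = "-"
        if consistent:
            response = "favored by disturbance" if implied[0] > 0 else \
                "negatively affected by disturbance"
        rows.append({"taxon_id": taxon, **labels,
                     "consistent": consistent, "response": response})
    return pd.DataFrame(
        rows, columns=["taxon_id", "abundance_dist_mine", "abundance_mining_cover",
                       "trend_dist_mine", "trend_mining_cover", "consistent",
                       "response"]
    )


class IndicatorScreen(BaseEstimator):
    """Both indicator tracks plus the consistency classification.

    Parameters
    ----------
    n_resample : PIT-trap iterations for the abundance track.
    buffer : buffer scale (m) for mining cover in the abundance track.
    min_caves : trend-track inclusion rule (>= 10 cave slopes).
    min_years : survey-span filter (>= 3 distinct years) for trend slopes.

    Fitted attributes
    -----------------
    abundance_effects_, trend_effects_, report_ : DataFrames; the report
    optionally carries each taxon's recommended sampling season when an
    effort summary is passed to :meth:`fit`.
    """

    def __init__(self, n_resample: int = 999, alpha: float = 0.05,
                 buffer: int = 1000, min_caves: int = 10, min_years: int = 3,
                 resample_unit: str = "cave", random_state=None):
        self.n_resample = n_resample
        self.alpha = alpha
        self.buffer = buffer
        self.min_caves = min_caves
        self.min_years = min_years
        self.resample_unit = resample_unit
        self.random_state = random_state

    def fit(self, table: SurveyTable, covariates: pd.DataFrame,
            season_recommendations: pd.DataFrame | None = None):
        matrix = to_community_matrix(table)
        self.abundance_effects_ = fit_species_glms(
            matrix, covariates, buffer=self.buffer,
            n_resample=self.n_resample, seed=self.random_state,
            resample_unit=self.resample_unit,
        )
        self.slopes_ = per_cave_trend_slopes(table, self.min_years)
        self.trend_effects_ = trend_vs_disturbance(
            self.slopes_, covariates, self.min_caves
        )
        report = classify_indicators(
            self.abundance_effects_, self.trend_effects_, self.alpha
        )
        if season_recommendations is not None and len(season_recommendations):
            report = report.merge(
                season_recommendations.rename(
                    columns={"recommended_season": "sampling_season"}
                )[["taxon_id", "sampling_season"]],
                on="taxon_id", how="left",
            )
        self.report_ = report
        return self
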
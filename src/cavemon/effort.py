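"""Survey-effort subsampling: how many surveys, and in which season,
are needed to recover the full-data temporal abundance trend.

For every (cave, taxon, season) with at least three surveys, the
full-data OLS trend slope is the reference. For each subset size
k = 2 .. K, k surveys are drawn without replacement (ten draws by
default), the slope is refit on each draw, and the RMSE between the
full slope and the subset slopes is recorded. A curve that flattens at
small k means few surveys already pin down the trend; comparing the dry
and rainy curves per taxon yields a recommended sampling season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import stats as cs
from .data import SEASONS, SurveyTable

__all__ = [
    "RMSECurve",
    "EffortRecommendation",
    "EffortOptimizer",
    "full_trend_slope",
    "subsample_rmse",
    "rmse_curve",
    "stabilization_k",
    "season_summary",
]


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on t (with intercept)."""
    tc = t - t.mean()
    return float((tc @ (y - y.mean())) / (tc @ tc))


def full_trend_slope(records: pd.DataFrame) -> float:
    """Full-data OLS trend slope (individuals/year) for one
    cave x taxon x season; requires >= 3 surveys on >= 2 distinct dates."""
    t = records["t"].to_numpy(dtype=float)
    y = records["count"].to_numpy(dtype=float)
    if len(t) < 3:
        raise cs.InsufficientDataError("need at least three surveys")
    if len(np.unique(t)) < 2:
        raise cs.CollinearityError("all surveys on the same date")
    return cs.ols_fit(y, np.column_stack([np.ones_like(t), t])).slope


def _subset_stats(t, y, k, n_draws, rng, full_slope, full_intercept=None):
    """Subset slopes (and optionally intercept deviations) for rmse."""
    n = len(t)
    estimates = []
    for _ in range(n_draws):
        for _attempt in range(100):
            idx = rng.choice(n, size=k, replace=False)
            if len(np.unique(t[idx])) >= 2:
                break
        else:
            continue  # all attempts degenerate: drop this draw
        ts, ys = t[idx], y[idx]
        s = _slope(ts, ys)
        if full_intercept is None:
            estimates.append(s)
        else:
            b0 = ys.mean() - s * ts.mean()
            estimates.append(np.hypot(s - full_slope, b0 - full_intercept))
    return estimates


def subsample_rmse(records: pd.DataFrame, k: int, n_draws: int = 10,
                   seed=None, include_intercept: bool = False) -> float:
    """RMSE between the full-data trend slope and slopes from k-survey
    random subsets (without replacement).

    Draws in which every sampled survey falls on one date cannot yield a
    slope; such draws are redrawn (up to 100 attempts, then dropped).
    """
    t = records["t"].to_numpy(dtype=float)
    y = records["count"].to_numpy(dtype=float)
    K = len(t)
    if not 2 <= k <= K:
        raise ValueError(f"k={k} outside [2, {K}]")
    full = cs.ols_fit(y, np.column_stack([np.ones_like(t), t]))
    rng = np.random.default_rng(seed)
    if include_intercept:
        devs = _subset_stats(t, y, k, n_draws, rng, full.slope,
                             float(full.coefficients[0]))
        if not devs:
            raise ValueError("every draw degenerate; rmse undefined")
        return float(np.sqrt(np.mean(np.square(devs))))
    slopes = _subset_stats(t, y, k, n_draws, rng, full.slope)
    if not slopes:
        raise ValueError("every draw degenerate; rmse undefined")
    return cs.rmse(full.slope, slopes)


@dataclass
class RMSECurve:
    """RMSE-vs-effort curve for one cave x taxon x season."""

    cave_id: str
    taxon_id: str
    season: str
    k_values: np.ndarray
    rmse_values: np.ndarray
    K: int
    n_draws: int
    full_slope: float


def rmse_curve(records: pd.DataFrame, n_draws: int = 10, seed=None,
               include_intercept: bool = False) -> RMSECurve:
    """Compute :class:`RMSECurve` for k = 2 .. K (K = surveys available)."""
    t = records["t"].to_numpy(dtype=float)
    y = records["count"].to_numpy(dtype=float)
    K = len(t)
    if K < 3:
        raise cs.InsufficientDataError("need at least three surveys")
    if len(np.unique(t)) < 2:
        raise cs.CollinearityError("all surveys on the same date")
    rng = np.random.default_rng(seed)
    full = cs.ols_fit(y, np.column_stack([np.ones_like(t), t]))
    ks = np.arange(2, K + 1)
    vals = []
    for k in ks:
        if include_intercept:
            devs = _subset_stats(t, y, int(k), n_draws, rng, full.slope,
                                 float(full.coefficients[0]))
            vals.append(float(np.sqrt(np.mean(np.square(devs)))))
        else:
            slopes = _subset_stats(t, y, int(k), n_draws, rng, full.slope)
            vals.append(cs.rmse(full.slope, slopes))
    return RMSECurve(
        cave_id=str(records["cave_id"].iloc[0]),
        taxon_id=str(records["taxon_id"].iloc[0]),
        season=str(records["season"].iloc[0]),
        k_values=ks, rmse_values=np.asarray(vals), K=K,
        n_draws=n_draws, full_slope=full.slope,
    )


def stabilization_k(curve: RMSECurve, rel_tol: float = 0.1) -> int:
    """Smallest k after which successive RMSE changes stay small.

    Small means |rmse(k') - rmse(k'+1)| <= rel_tol * rmse(2) for every
    k' >= k. A flat-zero curve (rmse(2) = 0) stabilizes immediately at 2.
    """
    r = np.asarray(curve.rmse_values, dtype=float)
    ks = np.asarray(curve.k_values)
    if r[0] == 0:
        return 2
    thresh = rel_tol * r[0]
    diffs = np.abs(np.diff(r))
    ok = diffs <= thresh
    # last index where the condition fails; stabilize just after it
    bad = np.where(~ok)[0]
    if bad.size == 0:
        return int(ks[0])
    return int(ks[bad[-1] + 1])


@dataclass
class EffortRecommendation:
    """Per-taxon effort recommendation aggregated over caves."""

    taxon_id: str
    recommended_k: int
    recommended_season: str  # dry, rainy or both
    mean_rmse: dict = field(default_factory=dict)  # season -> integrated mean rmse


def _mean_curve(curves: list) -> tuple[np.ndarray, np.ndarray]:
    """Mean rmse per k over caves (curves may have different K)."""
    all_k = np.unique(np.concatenate([c.k_values for c in curves]))
    means = []
    for k in all_k:
        vals = [c.rmse_values[c.k_values == k][0] for c in curves if k in c.k_values]
        means.append(float(np.mean(vals)))
    return all_k, np.asarray(means)


def season_summary(curves: list, rel_tol: float = 0.1) -> list:
    """Aggregate curves to one :class:`EffortRecommendation` per taxon.

    The recommended season is the one with the lower mean RMSE
    integrated (trapezoid) over the k-range both seasons share; an exact
    tie — or a single available season with identical counterpart — maps
    to "both". The recommended k is the median stabilization point.
    """
    by_taxon = {}
    for c in curves:
        by_taxon.setdefault(c.taxon_id, []).append(c)
    recs = []
    for taxon, cl in sorted(by_taxon.items()):
        by_season = {s: [c for c in cl if c.season == s] for s in SEASONS}
        integrated = {}
        for s, group in by_season.items():
            if not group:
                continue
            ks, means = _mean_curve(group)
            integrated[s] = (ks, means)
        if len(integrated) == 2:
            (kd, md), (kr, mr) = integrated["dry"], integrated["rainy"]
            common = np.intersect1d(kd, kr)
            if common.size >= 2:
                area = {
                    "dry": float(np.trapezoid(md[np.isin(kd, common)], common)),
                    "rainy": float(np.trapezoid(mr[np.isin(kr, common)], common)),
                }
            else:
                area = {"dry": float(md.mean()), "rainy": float(mr.mean())}
            if np.isclose(area["dry"], area["rainy"], rtol=0, atol=1e-12):
                season = "both"
            else:
                season = min(area, key=area.get)
        else:
            (only,) = integrated
            season = only
            area = {only: float(integrated[only][1].mean())}
        k_stab = [stabilization_k(c, rel_tol) for c in cl]
        rec_k = int(np.ceil(np.median(k_stab)))
        recs.append(EffortRecommendation(taxon, max(rec_k, 2), season, area))
    return recs


class EffortOptimizer(BaseEstimator):
    """Subsampling analysis over every eligible cave x taxon x season.

    Parameters
    ----------
    n_draws : random subsets per subset size k.
    min_surveys : inclusion rule (>= 3 surveys per season).
    rel_tol : stabilization tolerance, as a fraction of rmse at k = 2.
    include_intercept : compare (slope, intercept) jointly instead of
        the slope alone.
    random_state : seed; per-unit streams are derived deterministically.

    Fitted attributes
    -----------------
    curves_ : list of :class:`RMSECurve`.
    curves_frame_ : the same curves in long-format DataFrame form.
    recommendations_ : list of :class:`EffortRecommendation` per taxon.
    skipped_ : DataFrame of ineligible units with reasons.
    """

    def __init__(self, n_draws: int = 10, min_surveys: int = 3,
                 rel_tol: float = 0.1, include_intercept: bool = False,
                 random_state=None):
        self.n_draws = n_draws
        self.min_surveys = min_surveys
        self.rel_tol = rel_tol
        self.include_intercept = include_intercept
        self.random_state = random_state

    def fit(self, table: SurveyTable, y=None):
        ss = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        curves, skipped = [], []
        groups = table.df.groupby(["cave_id", "taxon_id", "season"],
                                  observed=True, sort=True)
        seeds = ss.spawn(groups.ngroups)
        for seed, ((cave, taxon, season), grp) in zip(seeds, groups):
            if len(grp) < self.min_surveys:
                skipped.append((cave, taxon, season, "fewer than min surveys"))
                continue
            if grp["t"].nunique() < 2:
                skipped.append((cave, taxon, season, "all surveys on one date"))
                continue
            curves.append(
                rmse_curve(grp, n_draws=self.n_draws, seed=seed,
                           include_intercept=self.include_intercept)
            )
        self.curves_ = curves
        self.curves_frame_ = pd.DataFrame(
            [
                {"cave_id": c.cave_id, "taxon_id": c.taxon_id, "season": c.season,
                 "k": int(k), "rmse": float(r), "K": c.K, "full_slope": c.full_slope}
                for c in curves
                for k, r in zip(c.k_values, c.rmse_values)
            ]
        )
        self.recommendations_ = season_summary(curves, self.rel_tol)
        self.skipped_ = pd.DataFrame(
            skipped, columns=["cave_id", "taxon_id", "season", "reason"]
        )
        return self

    @property
    def recommendations_frame_(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"taxon_id": r.taxon_id, "recommended_k": r.recommended_k,
                 "recommended_season": r.recommended_season}
                for r in self.recommendations_
            ]
        )
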
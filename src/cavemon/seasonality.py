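"""Per-cave x taxon screen for season-dependent abundance trends.

For each (cave, taxon) with at least five surveys in each season, fit
count ~ date + season + date:season by OLS and test the interaction
coefficient (the difference in trend slope, individuals/year, between
seasons). P-values are Benjamini-Hochberg adjusted jointly across all
fitted models: a single large family, since the screen's decision —
"can trends be detected regardless of season?" — is about the whole
monitoring program, not any one taxon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import stats as cs
from .data import SurveyTable, filter_min_surveys_per_season

__all__ = ["SeasonalityScreen", "fit_interaction", "screen_seasonality"]


def fit_interaction(records: pd.DataFrame) -> dict:
    """Fit the date x season interaction model for one cave x taxon.

    ``records`` must hold columns t, season, count for a single
    combination. Returns coefficient/raw_p plus per-season survey counts.
    Raises :class:`cavemon.stats.CollinearityError` when dates are
    constant within a season (the interaction is then unidentifiable).
    """
    t = records["t"].to_numpy(dtype=float)
    dry = (records["season"] == "dry").to_numpy(dtype=float)
    y = records["count"].to_numpy(dtype=float)
    for s, mask in (("dry", dry == 1), ("rainy", dry == 0)):
        if len(np.unique(t[mask])) < 2:
            raise cs.CollinearityError(f"dates constant within {s} season")
    X = np.column_stack([np.ones_like(t), t, dry, t * dry])
    fit = cs.ols_fit(y, X)
    return {
        "interaction_coefficient": float(fit.coefficients[3]),
        "raw_p": float(fit.t_pvalues[3]),
        "n_dry": int(dry.sum()),
        "n_rainy": int((1 - dry).sum()),
    }


class SeasonalityScreen(BaseEstimator):
    """Screen every eligible cave x taxon for a date x season interaction.

    Parameters
    ----------
    min_surveys_per_season : inclusion rule — at least this many distinct
        survey dates in each season (overfitting guard).
    alpha : significance level applied to the adjusted p-values.
    family : "joint" adjusts across all models at once (default);
        "per_taxon" adjusts within each taxon separately.

    Fitted attributes
    -----------------
    results_ : DataFrame (cave_id, taxon_id, interaction_coefficient,
        raw_p, adjusted_p, n_dry, n_rainy).
    skipped_ : DataFrame of combinations not fitted, with reason codes.
    n_significant_ : count of adjusted_p < alpha. The screen's decision
        contract is exactly this count (0 means trend detection is
        season-agnostic), never a biological claim.
    """

    def __init__(self, min_surveys_per_season: int = 5, alpha: float = 0.05,
                 family: str = "joint"):
        self.min_surveys_per_season = min_surveys_per_season
        self.alpha = alpha
        self.family = family

    def fit(self, table: SurveyTable, y=None):
        eligible = filter_min_surveys_per_season(table, self.min_surveys_per_season)
        rows, skipped = [], []
        for (cave, taxon), grp in eligible.df.groupby(
            ["cave_id", "taxon_id"], observed=True, sort=True
        ):
            try:
                res = fit_interaction(grp)
            except cs.CollinearityError as exc:
                skipped.append((cave, taxon, f"degenerate design: {exc}"))
                continue
            rows.append({"cave_id": cave, "taxon_id": taxon, **res})
        if rows:
            results = pd.DataFrame(rows)
            if self.family == "per_taxon":
                results["adjusted_p"] = results.groupby("taxon_id")["raw_p"].transform(
                    lambda p: cs.bh_adjust(p.to_numpy())
                )
            else:
                results["adjusted_p"] = cs.bh_adjust(results["raw_p"].to_numpy())
        else:
            results = pd.DataFrame(
                columns=["cave_id", "taxon_id", "interaction_coefficient",
                         "raw_p", "n_dry", "n_rainy", "adjusted_p"]
            )
        self.results_ = results
        self.skipped_ = pd.DataFrame(skipped, columns=["cave_id", "taxon_id", "reason"])
        self.n_significant_ = int((results["adjusted_p"] < self.alpha).sum())
        self.n_models_ = len(results)
        return self


def screen_seasonality(table: SurveyTable, min_per_season: int = 5,
                       alpha: float = 0.05) -> SeasonalityScreen:
    """Functional wrapper over :class:`SeasonalityScreen`."""
    return SeasonalityScreen(min_per_season, alpha).fit(table)
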
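"""Survey-table and covariate-table containers, I/O, validation and the
inclusion filters used by the downstream screens.

The central object is :class:`SurveyTable`: one row per cave x taxon x
survey date carrying a season label and a non-negative integer abundance
count. Absences are true absences (every target taxon is searched for at
every survey event), so zero counts are data, not missingness.

Dates are additionally encoded as decimal years since the earliest survey
in the dataset (column ``t``), which makes trend slopes read as
"individuals per year". Any affine date encoding gives the same tests;
this one gives interpretable units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SchemaError",
    "SurveyTable",
    "CommunityMatrix",
    "read_survey_csv",
    "read_covariates_csv",
    "filter_min_surveys_per_season",
    "filter_year_span",
    "to_community_matrix",
]

log = logging.getLogger(__name__)

SEASONS = ("dry", "rainy")

SURVEY_COLUMNS = ["cave_id", "taxon_id", "date", "season", "count"]
COVARIATE_COLUMNS = [
    "cave_id",
    "highland",
    "area_m2",
    "temperature_c",
    "rainfall_dev_mm",
    "forest_500",
    "canga_500",
    "mining_500",
    "forest_1000",
    "canga_1000",
    "mining_1000",
    "dist_mine_m",
    "year",
]


class SchemaError(ValueError):
    """An input file is missing a required column."""


def _decimal_years(dates: pd.Series) -> pd.Series:
    origin = dates.min()
    return (dates - origin).dt.days / 365.25


@dataclass(frozen=True)
class SurveyTable:
    """A validated long-format survey table.

    Attributes
    ----------
    df : DataFrame with columns cave_id, taxon_id, date (datetime),
        season, year, count (int), t (decimal years since first survey).
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dedupe: str = "max") -> "SurveyTable":
        """Validate a raw frame and resolve duplicate (cave, taxon, date) rows.

        Duplicates are resolved by keeping the maximum count (``max``, the
        conservative census reading: the larger simultaneous census is the
        better lower bound on true abundance) or by summing (``sum``).
        """
        missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"survey table missing column(s): {missing}")
        out = df.copy()
        out["date"] = pd.to_datetime(out["date"])
        counts = pd.to_numeric(out["count"], errors="coerce")
        bad = counts.isna() | (counts < 0) | (counts != np.round(counts))
        if bad.any():
            rows = out.index[bad].tolist()[:10]
            raise ValueError(f"non-negative integer counts required (rows {rows})")
        out["count"] = counts.astype(int)
        unknown = ~out["season"].isin(SEASONS)
        if unknown.any():
            labels = sorted(out.loc[unknown, "season"].unique().tolist())
            raise ValueError(f"unknown season label(s) {labels}; expected {SEASONS}")
        derived_year = out["date"].dt.year
        if "year" in out.columns:
            if (out["year"].astype(int) != derived_year).any():
                raise ValueError("year column disagrees with calendar year of date")
        out["year"] = derived_year

        key = ["cave_id", "taxon_id", "date"]
        n_dup = int(out.duplicated(key).sum())
        if n_dup:
            log.info("resolving %d duplicate (cave, taxon, date) rows by %s", n_dup, dedupe)
            agg = "max" if dedupe == "max" else "sum"
            out = (
                out.groupby(key + ["season", "year"], as_index=False, sort=False)
                .agg(count=("count", agg))
            )
        out = out[["cave_id", "taxon_id", "date", "season", "year", "count"]]
        out = out.sort_values(key, kind="stable").reset_index(drop=True)
        out["t"] = _decimal_years(out["date"])
        return cls(out)

    @property
    def taxa(self) -> list:
        return sorted(self.df["taxon_id"].unique().tolist())

    @property
    def caves(self) -> list:
        return sorted(self.df["cave_id"].unique().tolist())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def _subset(self, mask) -> "SurveyTable":
        # keep the original decimal-year origin so slopes stay comparable
        return SurveyTable(self.df[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        cols = ["cave_id", "taxon_id", "date", "season", "count"]
        out = self.df[cols].copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def read_survey_csv(path, dedupe: str = "max") -> SurveyTable:
    """Read and validate a long-format survey CSV."""
    return SurveyTable.from_frame(pd.read_csv(path), dedupe=dedupe)


def read_covariates_csv(path) -> pd.DataFrame:
    """Read and validate the per-cave (x year) covariate table."""
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate table missing column(s): {missing}")
    covers = [c for c in df.columns if c.split("_")[0] in ("forest", "canga", "mining")]
    for c in covers:
        if ((df[c] < 0) | (df[c] > 1)).any():
            raise ValueError(f"cover proportion {c} outside [0, 1]")
    if (df["area_m2"] <= 0).any():
        raise ValueError("cave area must be positive")
    if (df["dist_mine_m"] < 0).any():
        raise ValueError("distance to mine must be non-negative")
    return df


# ---------------------------------------------------------------------------
# inclusion filters


def filter_min_surveys_per_season(table: SurveyTable, min_k: int = 5) -> SurveyTable:
    """Keep (cave, taxon) combinations with >= min_k distinct survey dates
    in the dry season AND >= min_k in the rainy season.

    This is the overfitting guard for the seasonality screen; combinations
    surveyed predominantly in one season cannot support a date x season
    interaction fit.
    """
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    df = table.df
    k = (
        df.groupby(["cave_id", "taxon_id", "season"], observed=True)["date"]
        .nunique()
        .unstack("season", fill_value=0)
        .reindex(columns=list(SEASONS), fill_value=0)
    )
    keep = k.index[(k["dry"] >= min_k) & (k["rainy"] >= min_k)]
    mask = df.set_index(["cave_id", "taxon_id"]).index.isin(keep)
    if not mask.any():
        log.warning("season-count filter removed every (cave, taxon) combination")
    return table._subset(mask)


def filter_year_span(table: SurveyTable, min_years: int = 3) -> SurveyTable:
    """Keep (cave, taxon) combinations surveyed in >= min_years distinct
    calendar years (repeat surveys within a year do not add years)."""
    if min_years < 2:
        raise ValueError("min_years must be >= 2")
    df = table.df
    span = df.groupby(["cave_id", "taxon_id"], observed=True)["year"].nunique()
    keep = span.index[span >= min_years]
    mask = df.set_index(["cave_id", "taxon_id"]).index.isin(keep)
    if not mask.any():
        log.warning("year-span filter removed every (cave, taxon) combination")
    return table._subset(mask)


# ---------------------------------------------------------------------------
# community matrix


@dataclass
class CommunityMatrix:
    """Survey events x taxa abundance matrix with row metadata.

    ``counts`` rows are (cave, date) survey events; ``meta`` carries
    cave_id, date, season, year and decimal-year t, row-aligned with
    ``counts``. ``zero_rows`` flags events at which nothing was found.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    relative: bool = False

    @property
    def zero_rows(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy() == 0

    @property
    def taxa(self) -> list:
        return self.counts.columns.tolist()

    def to_long(self) -> pd.DataFrame:
        """Melt back to the long survey-record layout (counts only)."""
        long = self.counts.copy()
        long[["cave_id", "date"]] = self.meta[["cave_id", "date"]].to_numpy()
        long["season"] = self.meta["season"].to_numpy()
        return long.melt(
            id_vars=["cave_id", "date", "season"],
            var_name="taxon_id",
            value_name="count",
        )


def to_community_matrix(table: SurveyTable, relative: bool = False) -> CommunityMatrix:
    """Pivot a survey table to one row per (cave, date) survey event.

    Cells absent from the long table are zero-filled (true absences). With
    ``relative=True`` rows are divided by their totals; all-zero rows stay
    zero and are flagged via :attr:`CommunityMatrix.zero_rows`.
    """
    if table.n_records == 0:
        raise ValueError("cannot build a community matrix from an empty table")
    df = table.df
    wide = df.pivot_table(
        index=["cave_id", "date"],
        columns="taxon_id",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    meta = (
        df.groupby(["cave_id", "date"], observed=True)
        .agg(season=("season", "first"), year=("year", "first"), t=("t", "first"))
        .loc[wide.index]
        .reset_index()
    )
    counts = wide.reset_index(drop=True).astype(float)
    counts.columns.name = None
    if relative:
        tot = counts.sum(axis=1)
        if (tot == 0).any():
            log.info("%d all-zero survey events kept as zeros", int((tot == 0).sum()))
        counts = counts.div(tot.where(tot > 0, 1.0), axis=0)
    return CommunityMatrix(counts, meta, relative=relative)
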
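"""Partial redundancy analysis with permutation tests of marginal effects.

The community matrix (survey events x taxa, Hellinger-transformed
relative abundances) is regressed on standardized environmental and
landscape predictors after partialling out the highland a cave sits on
(a purely geographic blocking variable). Inertia is partitioned into a
conditional part (highland), a constrained part (the predictors) and a
residual; each term's marginal (type-III-like) contribution is tested by
permuting reduced-model residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import stats as cs
from .data import CommunityMatrix, SurveyTable, to_community_matrix

__all__ = [
    "HellingerTransformer",
    "PartialRDA",
    "partial_rda",
    "permutation_test_marginal",
    "build_rda_design",
    "run_rda",
]


class HellingerTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the Hellinger transform."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return cs.hellinger(X)


def _orth(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _constrained_ss(qx: np.ndarray, Y: np.ndarray) -> float:
    """Sum of squares of the projection of Y onto span(qx)."""
    proj = qx.T @ Y
    return float((proj * proj).sum())


class PartialRDA(BaseEstimator):
    """Partial RDA with marginal permutation tests.

    Parameters
    ----------
    n_permutations : permutations per marginal test; the smallest
        attainable p-value is 1/(n_permutations + 1). The string
        ``"exhaustive"`` enumerates all n! row permutations instead
        (tiny n only), giving exact permutation p-values.
    random_state : seed for the permutation stream.

    Fitted attributes
    -----------------
    terms_ : DataFrame with one row per term: df, variance, F, p_value.
    total_inertia_, conditional_inertia_, constrained_inertia_,
    residual_inertia_ : the variance decomposition (all on the
        sum-of-squares / (n - 1) scale, computed after conditioning for
        the constrained and residual parts).
    adjusted_r2_ : Ezekiel-adjusted semi-partial R².
    """

    def __init__(self, n_permutations: int = 999, random_state=None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, Y, X_terms: dict, Z=None):
        """Fit the ordination.

        Parameters
        ----------
        Y : (n, S) response matrix (already Hellinger-transformed).
        X_terms : mapping term name -> (n,) or (n, k) predictor block;
            blocks are tested jointly with df = k.
        Z : optional (n,) or (n, q) conditioning block (e.g. highland
            dummies); an intercept is always conditioned on.
        """
        exhaustive = self.n_permutations == "exhaustive"
        if not exhaustive and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        Y = np.asarray(Y, dtype=float)
        n = Y.shape[0]
        names = list(X_terms)
        blocks = []
        for name in names:
            b = np.asarray(X_terms[name], dtype=float)
            blocks.append(b[:, None] if b.ndim == 1 else b)
        if Z is None:
            Zm = np.ones((n, 1))
        else:
            Z = np.asarray(Z, dtype=float)
            Zm = np.column_stack([np.ones(n), Z if Z.ndim == 2 else Z[:, None]])

        qz = _orth(Zm)
        df_z = qz.shape[1] - 1  # conditioning df beyond the intercept
        Yc = Y - Y.mean(axis=0)
        total_raw = float((Yc * Yc).sum())
        Yres = Y - qz @ (qz.T @ Y)
        total_cond = float((Yres * Yres).sum())

        Xres = [b - qz @ (qz.T @ b) for b in blocks]
        X_all = np.column_stack(Xres)
        p_all = sum(b.shape[1] for b in Xres)
        if n <= p_all + df_z + 2:
            raise cs.InsufficientDataError(
                f"n={n} rows for {p_all} constrained + {df_z} conditioning df"
            )
        qx_all = _orth(X_all)
        if qx_all.shape[1] < p_all:
            raise cs.CollinearityError(
                "constrained predictors collinear after conditioning"
            )

        ss_all = _constrained_ss(qx_all, Yres)
        ss_resid = total_cond - ss_all
        df_resid = n - 1 - df_z - p_all
        denom = n - 1

        rng = np.random.default_rng(self.random_state)
        rows = []
        for i, name in enumerate(names):
            reduced = [b for j, b in enumerate(Xres) if j != i]
            q_red = _orth(np.column_stack(reduced)) if reduced else np.zeros((n, 0))
            df_t = Xres[i].shape[1]
            ss_red = _constrained_ss(q_red, Yres)
            ss_term = ss_all - ss_red
            f_obs = (ss_term / df_t) / (ss_resid / df_resid)
            p = self._perm_p(Yres, qx_all, q_red, df_t, df_resid, f_obs, rng)
            rows.append((name, df_t, ss_term / denom, f_obs, p))

        self.terms_ = pd.DataFrame(
            rows, columns=["term", "df", "variance", "F", "p_value"]
        )
        self.n_ = n
        self.total_inertia_ = total_raw / denom
        self.conditional_inertia_ = (total_raw - total_cond) / denom
        self.constrained_inertia_ = ss_all / denom
        self.residual_inertia_ = ss_resid / denom
        self.residual_df_ = df_resid
        r2 = ss_all / total_cond
        self.adjusted_r2_ = cs.adjusted_r2(r2, n - df_z, p_all)
        return self

    def _perm_p(self, Yres, qx_all, q_red, df_t, df_resid, f_obs, rng):
        """Reduced-model residual permutation p-value for one term."""
        n = Yres.shape[0]
        fit_red = q_red @ (q_red.T @ Yres)
        resid_red = Yres - fit_red
        if self.n_permutations == "exhaustive":
            from itertools import permutations as _perms
            from math import factorial

            perms = [np.asarray(p) for p in _perms(range(n))]
            count = sum(
                self._perm_f(fit_red, resid_red, p, qx_all, q_red, df_t, df_resid)
                >= f_obs - 1e-12
                for p in perms
            )
            return count / factorial(n)  # identity permutation is in the set
        count = 0
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            Yp = fit_red + resid_red[perm]
            ss_all_p = _constrained_ss(qx_all, Yp)
            ss_red_p = _constrained_ss(q_red, Yp)
            # residual SS of the permuted response under the full model
            ss_tot_p = float((Yp * Yp).sum()) - float(
                n * (Yp.mean(axis=0) ** 2).sum()
            )
            f_p = ((ss_all_p - ss_red_p) / df_t) / ((ss_tot_p - ss_all_p) / df_resid)
            if f_p >= f_obs - 1e-12:
                count += 1
        return (1 + count) / (1 + self.n_permutations)

    @staticmethod
    def _perm_f(fit_red, resid_red, perm, qx_all, q_red, df_t, df_resid):
        n = fit_red.shape[0]
        Yp = fit_red + resid_red[perm]
        ss_all_p = _constrained_ss(qx_all, Yp)
        ss_red_p = _constrained_ss(q_red, Yp)
        ss_tot_p = float((Yp * Yp).sum()) - float(n * (Yp.mean(axis=0) ** 2).sum())
        return ((ss_all_p - ss_red_p) / df_t) / ((ss_tot_p - ss_all_p) / df_resid)

    def summary(self) -> pd.DataFrame:
        """Ordination table: one row per term plus a residual row."""
        out = self.terms_.copy()
        out.loc[len(out)] = ("Residual", self.residual_df_, self.residual_inertia_,
                             np.nan, np.nan)
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def partial_rda(Y, X_terms, Z=None, n_permutations=999, random_state=None) -> PartialRDA:
    """Functional wrapper over :class:`PartialRDA`."""
    return PartialRDA(n_permutations=n_permutations, random_state=random_state).fit(
        Y, X_terms, Z
    )


def permutation_test_marginal(Y, X_terms, Z, term, n_perm=999, seed=None) -> float:
    """Marginal permutation p-value for a single named term."""
    model = PartialRDA(n_permutations=n_perm, random_state=seed).fit(Y, X_terms, Z)
    row = model.terms_.set_index("term").loc[term]
    return float(row["p_value"])


# ---------------------------------------------------------------------------
# assembling the design from monitoring tables


def _season_in_year(meta: pd.DataFrame, coding: str) -> np.ndarray:
    """Encode the season-nested-in-year term.

    ``contrast`` gives the single dry-vs-rainy contrast (1 df, matching a
    one-row ordination table); ``nested`` gives year dummies plus a
    per-year season contrast (the full year/season factor, tested
    jointly). The two codings answer slightly different questions and
    both are exposed.
    """
    dry = (meta["season"] == "dry").astype(float).to_numpy()
    if coding == "contrast":
        return dry[:, None]
    if coding != "nested":
        raise ValueError(f"unknown season coding {coding!r}")
    years = sorted(meta["year"].unique())
    cols = []
    for y in years[1:]:
        cols.append((meta["year"] == y).astype(float).to_numpy())
    for y in years:
        cols.append(dry * (meta["year"] == y).to_numpy())
    return np.column_stack(cols)


def build_rda_design(
    matrix: CommunityMatrix,
    covariates: pd.DataFrame,
    buffer: int = 1000,
    season_coding: str = "nested",
):
    """Build (Y, X_terms, Z) for the monitoring RDA.

    Y is the Hellinger transform of the event x taxa counts. Continuous
    predictors are standardized; land covers are taken at the requested
    buffer scale and matched to the survey year; Z is the highland dummy.
    """
    Y = cs.hellinger(matrix.counts.to_numpy())
    meta = matrix.meta
    cov = covariates.copy()
    years = np.sort(cov["year"].unique())
    match_year = np.clip(meta["year"].to_numpy(), years.min(), years.max())
    key = pd.DataFrame({"cave_id": meta["cave_id"], "year": match_year})
    merged = key.merge(cov, on=["cave_id", "year"], how="left", validate="many_to_one")
    if merged["area_m2"].isna().any():
        missing = sorted(key.loc[merged["area_m2"].isna(), "cave_id"].unique())
        raise ValueError(f"covariates missing for cave(s) {missing}")

    X_terms = {
        "season_in_year": _season_in_year(meta, season_coding),
        "canga_cover": cs.standardize(merged[f"canga_{buffer}"].to_numpy()),
        "forest_cover": cs.standardize(merged[f"forest_{buffer}"].to_numpy()),
        "mining_cover": cs.standardize(merged[f"mining_{buffer}"].to_numpy()),
        "dist_mine": cs.standardize(np.log(merged["dist_mine_m"].to_numpy())),
        "area": cs.standardize(np.log(merged["area_m2"].to_numpy())),
        "temperature": cs.standardize(merged["temperature_c"].to_numpy()),
        "rainfall_dev": cs.standardize(merged["rainfall_dev_mm"].to_numpy()),
    }
    Z = (merged["highland"] == merged["highland"].unique()[0]).astype(float).to_numpy()
    return Y, X_terms, Z


def run_rda(
    table: SurveyTable,
    covariates: pd.DataFrame,
    buffer: int = 1000,
    season_coding: str = "nested",
    n_permutations: int = 999,
    random_state=None,
) -> PartialRDA:
    """Full pipeline: survey table -> community matrix -> partial RDA."""
    matrix = to_community_matrix(table)
    Y, X_terms, Z = build_rda_design(matrix, covariates, buffer, season_coding)
    return PartialRDA(n_permutations=n_permutations, random_state=random_state).fit(
        Y, X_terms, Z
    )
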
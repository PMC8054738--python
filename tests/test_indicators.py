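"""Two-track indicator screen: resampling inference, trend second stage,
and the consistency classification."""

import numpy as np
import pandas as pd
import pytest

from cavemon import (
    SimulationConfig,
    classify_indicators,
    fit_species_glms,
    per_cave_trend_slopes,
    simulate_dataset,
    simulate_null_dataset,
    to_community_matrix,
    trend_vs_disturbance,
)
from cavemon.indicators import _stepdown_adjust
from cavemon.stats import lrt, ols_fit


# ---------------------------------------------------------------------------
# track A: abundance NB GLMs with PIT-trap resampling


def _sim(n_caves=12, n_taxa=4, seed=0, **kw):
    cfg = SimulationConfig(n_caves=n_caves, n_taxa=n_taxa, n_years=4,
                           surveys_per_season_per_year=1, seed=seed, **kw)
    return simulate_dataset(cfg)


def test_single_species_stepdown_is_identity():
    table, cov, _ = _sim(n_taxa=1, seed=3)
    m = to_community_matrix(table)
    out = fit_species_glms(m, cov, n_resample=49, seed=1)
    sub = out.dropna(subset=["raw_p"])
    np.testing.assert_allclose(sub["adjusted_p"], sub["raw_p"])


def test_injected_mining_effect_detected_with_sign():
    """One species with a strong negative mining-cover effect gets the
    smallest adjusted p in the family and a negative coefficient."""
    beta = np.zeros(5)
    beta[2] = -3.0
    table, cov, truth = _sim(
        n_caves=25, n_taxa=5, seed=8,
        beta_mine=beta, beta_dist=0.0, trend=0.0, gamma_mine=0.0, gamma_dist=0.0,
        baseline_log_abundance=2.0, season_effect=0.0,
    )
    m = to_community_matrix(table)
    out = fit_species_glms(m, cov, n_resample=99, seed=2)
    mc = out[out["term"] == "mining_cover"].set_index("taxon_id")
    target = truth.taxa[2]
    assert mc.loc[target, "coefficient"] < 0
    assert mc.loc[target, "adjusted_p"] == mc["adjusted_p"].min()
    assert mc.loc[target, "adjusted_p"] < 0.05


def test_null_community_raw_rejection_rate():
    """No disturbance effects: per-term raw rejection rate is consistent
    with the nominal 0.05 and p-values are not pathologically skewed."""
    table, cov, _ = simulate_null_dataset(
        SimulationConfig(n_caves=25, n_taxa=12, n_years=4,
                         surveys_per_season_per_year=1, seed=15)
    )
    m = to_community_matrix(table)
    out = fit_species_glms(m, cov, n_resample=99, seed=5)
    sub = out[out["term"].isin(["dist_mine", "mining_cover"])].dropna(subset=["raw_p"])
    rate = (sub["raw_p"] < 0.05).mean()
    n = len(sub)
    half = 2.576 * np.sqrt(0.05 * 0.95 / n)
    assert rate <= 0.05 + half
    assert 0.25 < sub["raw_p"].mean() < 0.75


def test_stepdown_properties(rng):
    """Step-down adjusted p-values dominate raw ones and are monotone in
    the observed statistics."""
    obs = rng.exponential(1.0, size=8)
    boot = rng.exponential(1.0, size=(199, 8))
    adj = _stepdown_adjust(obs, boot)
    raw = (1 + (boot >= obs[None, :] - 1e-12).sum(axis=0)) / 200
    assert np.all(adj >= raw - 1e-12)
    order = np.argsort(-obs)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all((adj > 0) & (adj <= 1))


# ---------------------------------------------------------------------------
# track B: per-cave slopes and second-stage regressions


def test_per_cave_slopes_signs_and_filter(small_table):
    slopes = per_cave_trend_slopes(small_table)
    df = small_table.df
    spans = df.groupby(["cave_id", "taxon_id"])["year"].nunique()
    expected_units = set(spans.index[spans >= 3])
    got_units = set(map(tuple, slopes[["cave_id", "taxon_id"]].values))
    assert got_units <= expected_units
    # delegation identity: slopes equal a direct OLS refit
    for _, row in slopes.head(5).iterrows():
        g = df[(df["cave_id"] == row["cave_id"]) & (df["taxon_id"] == row["taxon_id"])]
        X = np.column_stack([np.ones(len(g)), g["t"].to_numpy()])
        assert row["slope"] == pytest.approx(
            ols_fit(g["count"].to_numpy(dtype=float), X).slope
        )


def test_two_year_span_absent():
    import pandas as pd
    from cavemon import SurveyTable

    rows = [("A", "X", d, "dry", c) for d, c in
            [("2015-06-01", 1), ("2015-08-01", 3), ("2016-06-01", 5)]]
    table = SurveyTable.from_frame(
        pd.DataFrame(rows, columns=["cave_id", "taxon_id", "date", "season", "count"])
    )
    assert per_cave_trend_slopes(table).empty


def _slopes_frame(n_caves, slopes):
    return pd.DataFrame({
        "cave_id": [f"C{i:03d}" for i in range(n_caves)],
        "taxon_id": "X",
        "slope": slopes,
        "n_surveys": 8,
    })


def _cov_frame(n_caves, mining, dist=None):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "cave_id": [f"C{i:03d}" for i in range(n_caves)],
        "mining_1000": mining,
        "mining_500": mining,
        "dist_mine_m": dist if dist is not None else rng.uniform(200, 3000, n_caves),
        "year": 2015,
    })


def test_trend_construction_recovers_coefficient():
    """Slopes built as an exact linear function of mining cover: the
    second-stage p floors out and the coefficient matches construction."""
    rng = np.random.default_rng(4)
    mining = rng.uniform(0, 0.6, 15)
    slopes = 0.2 - 1.5 * mining
    out = trend_vs_disturbance(_slopes_frame(15, slopes), _cov_frame(15, mining))
    row = out[out["metric"] == "mining_cover"].iloc[0]
    assert row["lrt_p"] < 1e-10
    # coefficient is on the standardized metric
    assert row["coefficient"] == pytest.approx(-1.5 * mining.std(ddof=1), rel=1e-6)


def test_fewer_than_ten_caves_skipped():
    rng = np.random.default_rng(5)
    mining = rng.uniform(0, 0.6, 9)
    out = trend_vs_disturbance(_slopes_frame(9, rng.normal(size=9)),
                               _cov_frame(9, mining))
    assert out.empty
    out10 = trend_vs_disturbance(_slopes_frame(10, rng.normal(size=10)),
                                 _cov_frame(10, rng.uniform(0, 0.6, 10)))
    assert not out10.empty and (out10["n_caves"] == 10).all()


def test_second_stage_lrt_null_uniform(rng):
    """Slopes independent of the metric: LRT p-values across replicates
    behave like Uniform(0, 1) (rejection near nominal)."""
    ps = []
    for _ in range(300):
        y = rng.normal(size=25)
        x = rng.normal(size=25)
        full = ols_fit(y, np.column_stack([np.ones(25), x]))
        null = ols_fit(y, np.ones((25, 1)))
        ps.append(lrt(full.log_likelihood, null.log_likelihood, 1))
    rate = np.mean(np.asarray(ps) < 0.05)
    assert abs(rate - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 300) + 0.01


# ---------------------------------------------------------------------------
# classification


def _abund(taxon, term, coef, adj_p):
    return {"taxon_id": taxon, "term": term, "coefficient": coef,
            "ci_low": coef - 1, "ci_high": coef + 1, "lr_stat": 1.0,
            "raw_p": adj_p, "adjusted_p": adj_p, "converged": True}


def _trend(taxon, metric, coef, p):
    return {"taxon_id": taxon, "metric": metric, "scale": 1000, "cov_year": 2015,
            "coefficient": coef, "lrt_p": p, "log_likelihood": -1.0, "n_caves": 12}


def test_consistent_negative_indicator():
    """Significant negative mining effects in both tracks: consistent,
    negatively affected by disturbance."""
    ab = pd.DataFrame([_abund("X", "mining_cover", -0.8, 0.01),
                       _abund("X", "dist_mine", 0.5, 0.3)])
    tr = pd.DataFrame([_trend("X", "mining_cover", -0.4, 0.02),
                       _trend("X", "dist_mine", 0.3, 0.04)])
    rep = classify_indicators(ab, tr).set_index("taxon_id")
    assert bool(rep.loc["X", "consistent"])
    assert rep.loc["X", "response"] == "negatively affected by disturbance"
    # positive distance effect = negative disturbance direction: coherent
    assert rep.loc["X", "trend_dist_mine"] == "positive"


def test_one_track_only_not_consistent():
    ab = pd.DataFrame([_abund("X", "mining_cover", -0.8, 0.01)])
    tr = pd.DataFrame([_trend("X", "mining_cover", -0.4, 0.5)])
    rep = classify_indicators(ab, tr).set_index("taxon_id")
    assert not bool(rep.loc["X", "consistent"])


def test_conflicting_directions_not_consistent():
    ab = pd.DataFrame([_abund("X", "mining_cover", 0.8, 0.01)])
    tr = pd.DataFrame([_trend("X", "mining_cover", -0.4, 0.01)])
    rep = classify_indicators(ab, tr).set_index("taxon_id")
    assert not bool(rep.loc["X", "consistent"])


def test_no_effects_all_dashes():
    ab = pd.DataFrame([_abund("X", "mining_cover", 0.1, 0.9),
                       _abund("X", "dist_mine", 0.1, 0.8)])
    tr = pd.DataFrame([_trend("X", "mining_cover", 0.1, 0.7)])
    rep = classify_indicators(ab, tr).set_index("taxon_id")
    row = rep.loc["X"]
    assert list(row[["abundance_dist_mine", "abundance_mining_cover",
                     "trend_dist_mine", "trend_mining_cover"]]) == ["-"] * 4
    assert not bool(row["consistent"])
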
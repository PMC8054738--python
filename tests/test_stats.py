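"""Unit and property tests for the statistical primitives, each checked
against an independent route (closed form, statsmodels, or brute force)."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cavemon import stats as cs


# ---------------------------------------------------------------------------
# Hellinger


@pytest.mark.parametrize(
    "row, expected",
    [
        ([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5]),
        ([4, 0], [1.0, 0.0]),
        ([1, 3], [0.5, np.sqrt(3) / 2]),
    ],
)
def test_hellinger_closed_forms(row, expected):
    np.testing.assert_allclose(cs.hellinger([row])[0], expected)


def test_hellinger_zero_row_flagged():
    with pytest.warns(UserWarning, match="all-zero"):
        out = cs.hellinger([[0, 0], [1, 1]])
    np.testing.assert_array_equal(out[0], [0, 0])


def test_hellinger_rejects_negative():
    with pytest.raises(ValueError):
        cs.hellinger([[-1, 2]])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=6),
        min_size=1,
        max_size=8,
    ).filter(lambda m: len({len(r) for r in m}) == 1)
)
def test_hellinger_rows_unit_norm(matrix):
    """Rows with positive totals map onto the unit sphere."""
    out = cs.hellinger(matrix)
    sums = np.asarray(matrix).sum(axis=1)
    norms = np.linalg.norm(out, axis=1)
    np.testing.assert_allclose(norms[sums > 0], 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# standardize


def test_standardize_basic():
    np.testing.assert_allclose(cs.standardize([1.0, 2.0, 3.0]), [-1, 0, 1])


def test_standardize_constant_column_warns():
    with pytest.warns(UserWarning, match="constant"):
        out = cs.standardize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
    np.testing.assert_array_equal(out[:, 0], 0.0)


def test_standardize_idempotent(rng):
    x = rng.normal(size=(30, 3))
    once = cs.standardize(x)
    np.testing.assert_allclose(cs.standardize(once), once, atol=1e-12)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_hand_example():
    np.testing.assert_allclose(cs.bh_adjust([0.01, 0.04]), [0.02, 0.04])


def test_bh_single_p_identity():
    np.testing.assert_allclose(cs.bh_adjust([0.05]), [0.05])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cs.bh_adjust([0.5, 1.2])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_dominates_and_preserves_order(pvals):
    """Adjusted >= raw elementwise, capped at 1, ranking preserved."""
    p = np.asarray(pvals)
    adj = cs.bh_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_bh_matches_statsmodels(rng):
    p = rng.uniform(size=25)
    from statsmodels.stats.multitest import multipletests

    _, expected, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(cs.bh_adjust(p), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# rmse / adjusted R2 / LRT


@pytest.mark.parametrize(
    "ref, est, expected",
    [(1, [1, 1, 1], 0.0), (1, [0, 2], 1.0), (0, [3, 4], np.sqrt(12.5))],
)
def test_rmse_closed_forms(ref, est, expected):
    assert cs.rmse(ref, est) == pytest.approx(expected)


def test_rmse_empty_errors():
    with pytest.raises(ValueError):
        cs.rmse(0.0, [])


def test_adjusted_r2():
    assert cs.adjusted_r2(0.5, 11, 1) == pytest.approx(4.0 / 9.0)
    assert cs.adjusted_r2(1.0, 20, 3) == pytest.approx(1.0)
    assert cs.adjusted_r2(0.0, 20, 3) <= 0.0
    with pytest.raises(ValueError):
        cs.adjusted_r2(0.5, 4, 3)


def test_lrt_reference_values():
    assert cs.lrt(-10.0, -10.0, 1) == pytest.approx(1.0)
    assert cs.lrt(-8.0795, -10.0, 1) == pytest.approx(0.05, abs=1e-3)
    with pytest.raises(ValueError):
        cs.lrt(-10.0, -10.0, 0)


def test_lrt_coranks_with_f_test(rng):
    """On nested OLS pairs, the chi-square LRT p orders model pairs the
    same way as the exact F-test."""
    lrt_ps, f_ps = [], []
    for _ in range(30):
        n = 15
        x = rng.normal(size=n)
        y = 1.0 + rng.uniform(0, 0.6) * x + rng.normal(size=n)
        full = cs.ols_fit(y, np.column_stack([np.ones(n), x]))
        null = cs.ols_fit(y, np.ones((n, 1)))
        lrt_ps.append(cs.lrt(full.log_likelihood, null.log_likelihood, 1))
        f_ps.append(float(full.t_pvalues[1]))  # t^2 == F for one coefficient
    assert sps.spearmanr(lrt_ps, f_ps).statistic > 0.999


# ---------------------------------------------------------------------------
# OLS


def test_ols_perfect_line():
    fit = cs.ols_fit([0, 1, 2], np.column_stack([np.ones(3), [0, 1, 2]]))
    np.testing.assert_allclose(fit.coefficients, [0, 1], atol=1e-12)
    np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)


def test_ols_intercept_only_is_mean(rng):
    y = rng.normal(size=9)
    fit = cs.ols_fit(y, np.ones((9, 1)))
    assert fit.coefficients[0] == pytest.approx(y.mean())


def test_ols_matches_normal_equations_and_statsmodels(rng):
    """Dual oracle: (X'X)^{-1}X'y and statsmodels OLS."""
    X = np.column_stack([np.ones(8), rng.normal(size=8), rng.normal(size=8)])
    y = rng.normal(size=8)
    fit = cs.ols_fit(y, X)
    beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.coefficients, beta_ne, atol=1e-10)
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-10)
    np.testing.assert_allclose(fit.t_pvalues, ref.pvalues, atol=1e-10)
    assert fit.log_likelihood == pytest.approx(ref.llf)


def test_ols_residuals_orthogonal_to_design(rng):
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
    y = rng.normal(size=40)
    fit = cs.ols_fit(y, X)
    assert np.max(np.abs(X.T @ fit.residuals)) < 1e-8 * np.abs(y).sum()


def test_ols_errors():
    with pytest.raises(cs.InsufficientDataError):
        cs.ols_fit([1.0, 2.0], np.ones((2, 3)))
    X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(cs.CollinearityError):
        cs.ols_fit(np.arange(5.0), X)


# ---------------------------------------------------------------------------
# negative binomial GLM


def test_nb_intercept_only_mean_matching():
    fit = cs.nb_glm_fit([3, 3, 3, 3], np.ones((4, 1)))
    assert fit.coefficients[0] == pytest.approx(np.log(3), abs=1e-6)


def test_nb_poisson_limit(rng):
    """Poisson data drive the fitted dispersion toward the Poisson limit:
    the implied excess variance mu/theta is negligible in every draw, and
    under-dispersed draws push theta to the cap."""
    thetas, mus = [], []
    for _ in range(10):
        y = rng.poisson(8.0, size=2000)
        fit = cs.nb_glm_fit(y, np.ones((2000, 1)))
        thetas.append(fit.theta)
        mus.append(np.exp(fit.coefficients[0]))
    inflation = np.asarray(mus) / np.asarray(thetas)
    assert np.all(inflation < 0.1)
    assert np.max(thetas) > 1e3


def test_nb_matches_grid_search_loglik(rng):
    """10-point dataset: ML log-likelihood within 1e-4 of a brute-force
    grid search over (intercept, slope, theta)."""
    x = np.linspace(0, 1, 10)
    y = np.array([2, 1, 4, 3, 5, 2, 7, 6, 9, 5])
    X = np.column_stack([np.ones(10), x])
    fit = cs.nb_glm_fit(y, X)

    def ll(b0, b1, th):
        mu = np.exp(b0 + b1 * x)
        return sps.nbinom.logpmf(y, th, th / (th + mu)).sum()

    grid = max(
        ll(b0, b1, th)
        for b0 in np.linspace(0.5, 2.0, 61)
        for b1 in np.linspace(-0.5, 1.8, 60)
        for th in np.exp(np.linspace(np.log(0.5), np.log(200), 60))
    )
    assert fit.log_likelihood >= grid - 1e-4


def test_nb_matches_statsmodels(rng):
    x = rng.normal(size=80)
    mu = np.exp(1.0 + 0.5 * x)
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    X = np.column_stack([np.ones(80), x])
    fit = cs.nb_glm_fit(y, X)
    ref = sm.NegativeBinomial(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params[:2], atol=2e-3)
    assert fit.theta == pytest.approx(1.0 / ref.params[-1], rel=0.02)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-3)


def test_nb_loglik_monotone_over_outer_iterations(rng):
    x = rng.normal(size=60)
    y = rng.negative_binomial(1.5, 1.5 / (1.5 + np.exp(0.8 + 0.6 * x)))
    y[0] = max(y[0], 1)
    fit = cs.nb_glm_fit(y, np.column_stack([np.ones(60), x]))
    assert np.all(np.diff(fit.ll_history) >= -1e-6)


def test_nb_rejects_bad_input():
    with pytest.raises(ValueError):
        cs.nb_glm_fit([0, 0, 0], np.ones((3, 1)))
    with pytest.raises(ValueError):
        cs.nb_glm_fit([1.5, 2.0], np.ones((2, 1)))
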
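"""Statistical primitives shared by every analysis stage.

Ordinary least squares with Gaussian maximum-likelihood log-likelihoods,
negative-binomial GLMs on the log link, the Hellinger transform,
column standardization, Benjamini-Hochberg adjustment, RMSE, the
likelihood-ratio test and the Ezekiel adjusted R².

The OLS and NB fits are deliberately lightweight numpy/scipy
implementations: the screening stages fit thousands of small models per
run, and the resampling-based inference refits the NB model hundreds of
times per species. Both are cross-validated against statsmodels in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "OLSFit",
    "NBFit",
    "InsufficientDataError",
    "CollinearityError",
    "hellinger",
    "standardize",
    "bh_adjust",
    "rmse",
    "ols_fit",
    "lrt",
    "nb_glm_fit",
    "adjusted_r2",
]

#: Dispersion cap: theta above this is numerically the Poisson limit.
THETA_MAX = 1e6
THETA_MIN = 1e-4


class InsufficientDataError(ValueError):
    """Fewer observations than parameters."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# transforms


def hellinger(counts) -> np.ndarray:
    """Hellinger-transform a site x species count matrix.

    Each cell becomes sqrt(count / row total). Rows summing to zero are
    left as zeros (a surveyed event at which nothing was found carries no
    compositional information) and trigger a warning.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hellinger transform requires non-negative counts")
    rowsum = x.sum(axis=1, keepdims=True)
    zero = rowsum[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows left untransformed")
    safe = np.where(rowsum == 0, 1.0, rowsum)
    return np.sqrt(x / safe)


def standardize(x) -> np.ndarray:
    """Center and scale columns to mean 0, SD 1 (n-1 denominator).

    Constant columns cannot be scaled; they are returned as all zeros
    with a warning so a downstream fit fails loudly on rank rather than
    silently dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant columns standardized to zeros")
    out = (x - mu) / np.where(const, 1.0, sd)
    out[:, const] = 0.0
    return out[:, 0] if one_d else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def rmse(reference: float, estimates) -> float:
    """Root mean squared deviation of estimates from a reference value."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("rmse requires at least one estimate")
    return float(np.sqrt(np.mean((est - reference) ** 2)))


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - r2) (n - 1) / (n - m - 1)."""
    if n <= m + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


# ---------------------------------------------------------------------------
# OLS


@dataclass
class OLSFit:
    """A least-squares fit with Gaussian ML log-likelihood.

    ``log_likelihood`` uses the ML variance estimate RSS/n (not REML), so
    differences between nested fits are valid likelihood-ratio statistics.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_pvalues: np.ndarray
    log_likelihood: float
    n: int
    df_residual: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def slope(self) -> float:
        """Convenience: the second coefficient (date slope in trend fits)."""
        return float(self.coefficients[1])


def _check_design(X: np.ndarray, n: int, p: int) -> None:
    if n <= p:
        raise InsufficientDataError(f"n={n} observations for p={p} parameters")
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns via near-zero diagonal of R in a QR
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = np.where(r < 1e-10 * max(r.max(), 1.0))[0]
        raise CollinearityError(f"design is rank deficient (columns {bad.tolist()})")


def ols_fit(y, X) -> OLSFit:
    """Ordinary least squares of y on a design matrix (incl. intercept column).

    Returns coefficients, standard errors, two-sided t-test p-values and
    the Gaussian ML log-likelihood.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    _check_design(X, n, p)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny  # perfect fit: ll diverges, clamp
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    if df_resid > 0:
        se = np.sqrt(np.diag(xtx_inv) * rss / df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            # se = 0 only for an exact fit: a zero coefficient then carries
            # no evidence (p = 1), a nonzero one is exact (p = 0)
            t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        pvals = 2 * sps.t.sf(np.abs(t), df_resid)
    else:
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return OLSFit(beta, se, pvals, float(ll), n, df_resid, resid, fitted)


def lrt(loglik_full: float, loglik_null: float, df_diff: int) -> float:
    """Likelihood-ratio test p-value from a chi-square reference.

    A slightly negative deviance (numerical noise from independently
    optimized fits) is clamped to zero.
    """
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    stat = 2.0 * (loglik_full - loglik_null)
    if stat < -1e-6 * max(1.0, abs(loglik_null)):
        raise ValueError(
            f"full-model log-likelihood below null ({loglik_full} < {loglik_null})"
        )
    return float(sps.chi2.sf(max(stat, 0.0), df_diff))


# ---------------------------------------------------------------------------
# negative binomial GLM


@dataclass
class NBFit:
    """Negative binomial (NB2) GLM fit on the log link.

    ``theta`` is the size/dispersion parameter: Var(y) = mu + mu^2/theta.
    ``theta`` at :data:`THETA_MAX` means the data are Poisson-consistent.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    theta: float
    log_likelihood: float
    converged: bool
    n: int
    df_model: int
    ll_history: np.ndarray = field(repr=False, default=None)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(sps.nbinom.logpmf(y, theta, theta / (theta + mu)).sum())


def _irls_nb(y, X, beta, theta, tol=1e-10, max_iter=50):
    """IRLS for NB regression coefficients at fixed theta."""
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        xtw = X.T * w
        new = np.linalg.solve(xtw @ X, xtw @ z)
        if np.max(np.abs(new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta


def nb_glm_fit(y, X, theta: float | None = None) -> NBFit:
    """Fit an NB2 GLM by alternating IRLS (coefficients) and 1-D ML (theta).

    Parameters
    ----------
    y : array of non-negative integer counts
    X : design matrix including the intercept column
    theta : if given, the dispersion is held fixed (used by the
        resampling machinery, where theta is pinned at the observed fit).

    The outer loop stops when the log-likelihood changes by less than a
    relative 1e-8, within 100 iterations; ``converged`` reports whether
    it did. Non-convergence is flagged, never raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if np.all(y == 0):
        raise ValueError("all-zero response: NB model undefined")
    _check_design(X, n, p)

    # moment start for theta; log(y + 0.5) least squares for beta
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)
    if theta is not None:
        th = float(theta)
        fixed = True
    else:
        m, v = y.mean(), y.var()
        th = np.clip(m * m / (v - m) if v > m else THETA_MAX, 1.0, THETA_MAX)
        fixed = False

    history = []
    ll_prev = -np.inf
    converged = False
    for _ in range(100):
        beta = _irls_nb(y, X, beta, th)
        mu = np.exp(np.clip(X @ beta, -30, 30))
        if not fixed:
            res = minimize_scalar(
                lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
                bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            th = float(np.exp(res.x))
        ll = _nb_loglik(y, mu, th)
        history.append(ll)
        if np.isfinite(ll) and abs(ll - ll_prev) < 1e-8 * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll

    # observed-information (Fisher) standard errors at fixed theta
    w = mu / (1.0 + mu / th)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return NBFit(beta, se, th, ll, converged, n, p, np.asarray(history))
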
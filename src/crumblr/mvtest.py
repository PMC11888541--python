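"""Multivariate combination of per-cluster effects.

Three p-value/effect combiners are provided: the Sidak correction of the
smallest p-value, Fisher's chi-square combination, and the Lin-Sullivan
correlated fixed-effects meta-analysis

    T = (1' W B)^2 / (1' W 1),   W = Omega^{-1},

which is asymptotically chi-square with 1 df under the null.  Because the
chi-square null is anti-conservative when Omega is estimated from few
samples, a finite-sample null is available: draw V ~ Wishart(Omega, nu),
b ~ N(0, V), recompute T, fit a gamma to the draws, and read the empirical
p-value off the gamma tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MultivariateTestResult",
    "EmpiricalNull",
    "sidak",
    "fisher",
    "lin_sullivan",
    "empirical_null",
    "ls_empirical_pvalue",
]


@dataclass
class MultivariateTestResult:
    statistic: float
    p_value: float
    method: str
    m: int
    combined_effect: float | None = None


@dataclass
class EmpiricalNull:
    """Monte-Carlo null of the Lin-Sullivan statistic summarized by a gamma fit."""

    draws: np.ndarray
    gamma_shape: float
    gamma_scale: float
    n_draws: int
    seed: int

    def sf(self, statistic: float) -> float:
        return float(stats.gamma.sf(statistic, self.gamma_shape, scale=self.gamma_scale))


def sidak(p_values: np.ndarray) -> MultivariateTestResult:
    """Smallest p-value corrected for the number of tests: 1 - (1 - min p)^m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pmin = float(p.min())
    # -expm1(m*log1p(-p)) is accurate for small pmin
    adj = -np.expm1(m * np.log1p(-pmin)) if pmin < 1 else 1.0
    return MultivariateTestResult(pmin, float(adj), "sidak", m)


def fisher(p_values: np.ndarray) -> MultivariateTestResult:
    """Fisher combination: -2 sum log p against chi-square with 2m df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any():
        raise ValueError("p-value of 0 gives an infinite statistic")
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    pval = float(stats.chi2.sf(stat, 2 * p.size))
    return MultivariateTestResult(stat, pval, "fisher", p.size)


def _solve_pd(omega: np.ndarray, rhs: np.ndarray, ridge: bool) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(omega)
        return scipy.linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError as err:
        if not ridge:
            raise ValueError(
                "singular covariance matrix; pass ridge=True to stabilize"
            ) from err
        eps = 1e-8 * float(np.mean(np.diag(omega)))
        logger.info("applying ridge %.3g to near-singular covariance", eps)
        return np.linalg.solve(omega + eps * np.eye(omega.shape[0]), rhs)


def lin_sullivan(
    betas: np.ndarray, omega: np.ndarray, ridge: bool = False
) -> MultivariateTestResult:
    """Correlated fixed-effects meta-analysis of m coefficient estimates.

    With diagonal omega this is classical inverse-variance meta-analysis.
    The combined effect is (1' W B) / (1' W 1) with W = omega^{-1}.
    """
    b = np.asarray(betas, dtype=float)
    O = np.asarray(omega, dtype=float)
    m = b.size
    if O.shape != (m, m):
        raise ValueError("omega shape must match betas")
    ones = np.ones(m)
    sol = _solve_pd(O, np.column_stack([b, ones]), ridge)
    num = float(ones @ sol[:, 0])
    den = float(ones @ sol[:, 1])
    if den <= 0:
        raise ValueError("covariance matrix is not positive definite")
    stat = num * num / den
    effect = num / den
    pval = float(stats.chi2.sf(stat, 1))
    return MultivariateTestResult(stat, pval, "LS_asymptotic", m, effect)


def _ls_statistics_batch(Vs: np.ndarray, bs: np.ndarray) -> np.ndarray:
    """Vectorized LS statistic for stacked covariances Vs (k,m,m) and draws bs (k,m)."""
    k, m = bs.shape
    ones = np.broadcast_to(np.ones(m), (k, m))
    rhs = np.stack([bs, ones], axis=-1)          # (k, m, 2)
    sol = np.linalg.solve(Vs, rhs)               # (k, m, 2)
    num = sol[:, :, 0].sum(axis=1)
    den = sol[:, :, 1].sum(axis=1)
    return num * num / den


def empirical_null(
    omega: np.ndarray,
    nu: float,
    n_draws: int = 10000,
    seed: int = 0,
    keep_draws: bool = True,
) -> EmpiricalNull:
    """Monte-Carlo finite-sample null of the Lin-Sullivan statistic.

    Each draw mimics one null replicate of the test: V ~ Wishart(scale =
    omega/nu, df = nu) plays the role of the covariance *estimate* that the
    statistic would be computed with (E[V] = omega), b ~ N(0, omega) plays
    the null coefficient estimates, and the statistic is LS(b, V).  The
    mismatch between the drawn V and the covariance of b is exactly what
    inflates the chi-square(1) approximation at small nu.  (Computing each
    statistic against the same V its b was drawn from would be exactly
    chi-square(1) for every V and could not capture that inflation.)
    A two-parameter gamma is fitted to the draws by maximum likelihood
    (moment start, moment fallback).
    """
    O = np.asarray(omega, dtype=float)
    m = O.shape[0]
    if nu < m:
        raise ValueError(f"need nu >= m for a nondegenerate Wishart (nu={nu}, m={m})")
    rng = np.random.default_rng(seed)
    Vs = stats.wishart.rvs(df=nu, scale=O / nu, size=n_draws, random_state=rng)
    Vs = Vs.reshape(n_draws, m, m)
    L = np.linalg.cholesky(O)
    bs = rng.standard_normal((n_draws, m)) @ L.T
    draws = _ls_statistics_batch(Vs, bs)
    shape, scale = _fit_gamma(draws)
    return EmpiricalNull(
        draws=draws if keep_draws else np.empty(0),
        gamma_shape=shape,
        gamma_scale=scale,
        n_draws=n_draws,
        seed=seed,
    )


def _fit_gamma(draws: np.ndarray) -> tuple[float, float]:
    mean, var = float(draws.mean()), float(draws.var())
    mom = (mean * mean / var, var / mean)
    try:
        shape, _, scale = stats.gamma.fit(draws, mom[0], floc=0, scale=mom[1])
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError
        return float(shape), float(scale)
    except Exception:
        logger.warning("gamma MLE failed; falling back to moment estimates")
        return mom


def ls_empirical_pvalue(
    betas: np.ndarray,
    omega: np.ndarray,
    nu: float,
    n_draws: int = 10000,
    seed: int = 0,
    null: EmpiricalNull | None = None,
    ridge: bool = False,
) -> MultivariateTestResult:
    """Lin-Sullivan test with the finite-sample Monte-Carlo null.

    The observed statistic is computed against the estimated omega; its
    p-value is the fitted-gamma tail probability.  A precomputed
    ``EmpiricalNull`` can be passed to amortize the draws.
    """
    res = lin_sullivan(betas, omega, ridge=ridge)
    if null is None:
        null = empirical_null(omega, nu, n_draws=n_draws, seed=seed, keep_draws=False)
    return MultivariateTestResult(
        res.statistic, null.sf(res.statistic), "LS_empirical", res.m, res.combined_effect
    )
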
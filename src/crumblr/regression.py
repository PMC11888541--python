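"""Precision-weighted regression per cluster with empirical-Bayes moderation.

Each cluster's CLR values are regressed on the sample covariates with the
regularized precision weights.  Residual variances are shrunk across
clusters with an inverse-gamma (scaled inverse chi-square) empirical-Bayes
prior, giving moderated t-statistics.  The covariance of a chosen
coefficient across clusters — needed for the multivariate test — follows the
weighted multivariate-regression form

    cov(b_i, b_j) = (r_i' r_j / d) (Xi'Xi)^{-1} Xi'Xj (Xj'Xj)^{-1}

with tilded (sqrt-weight scaled) quantities; with equal weights this is the
classical cov(vec(B)) = cov(R) kron (X'X)^{-1}.  Random-intercept models are
fitted by REML with known per-observation precision weights, and their
cross-cluster covariance uses cor(r_i, r_j) * sqrtm(S_i) sqrtm(S_j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .clr import CrumblrResult
from .data_model import ModelSpec, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "WLSFit",
    "LMMFit",
    "EBPrior",
    "CoefCovariance",
    "FitResult",
    "fit_weighted_lm",
    "fit_weighted_lmm",
    "cross_covariance",
    "lmm_cross_covariance",
    "eb_moderate",
    "fit_composition",
]


# ---------------------------------------------------------------- fixed effects


@dataclass
class WLSFit:
    """Weighted least-squares fit for one cluster."""

    beta: np.ndarray
    columns: list[str]
    xtx_inv: np.ndarray          # (Xw' Xw)^{-1}
    Xw: np.ndarray               # sqrt(w)-scaled design
    resid_weighted: np.ndarray   # yw - Xw beta
    df: float                    # n - c
    sigma2: float
    weights: np.ndarray

    @property
    def Sigma(self) -> np.ndarray:
        """Covariance of the coefficient estimates."""
        return self.sigma2 * self.xtx_inv

    @property
    def resid_whitened(self) -> np.ndarray:
        return self.resid_weighted


def _collinear_columns(Xw: np.ndarray, columns: list[str]) -> list[str]:
    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [columns[j] for j in piv[rank:]]


def fit_weighted_lm(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    w: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> WLSFit:
    """Fit y ~ X by weighted least squares with precision weights w.

    Minimizes sum_j w_j (y_j - x_j b)^2.  With all weights equal to 1 this
    is ordinary least squares.
    """
    if isinstance(X, pd.DataFrame):
        columns = columns or list(X.columns)
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, c = X.shape
    columns = columns or [f"x{j}" for j in range(c)]
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if len(y) != n or len(w) != n:
        raise ValueError("y, X and w must have matching lengths")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    if np.linalg.matrix_rank(Xw) < c:
        bad = _collinear_columns(Xw, columns)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - c
    if df <= 0:
        raise ValueError("need more samples than coefficients")
    sigma2 = float(resid @ resid) / df
    return WLSFit(beta, columns, xtx_inv, Xw, resid, float(df), sigma2, w)


@dataclass
class CoefCovariance:
    """Cross-cluster covariance of one coefficient's estimates."""

    omega: np.ndarray
    nu: float
    betas: np.ndarray
    clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        O = np.asarray(self.omega, dtype=float)
        if not np.allclose(O, O.T, atol=1e-8):
            raise ValueError("omega must be symmetric")
        self.omega = 0.5 * (O + O.T)
        if (np.diag(self.omega) <= 0).any():
            raise ValueError("omega diagonal must be positive")


def cross_covariance(
    fits: list[WLSFit] | dict[str, WLSFit],
    coef: str | int,
    clusters: list[str] | None = None,
) -> CoefCovariance:
    """Covariance matrix of one coefficient's estimates across clusters.

    All fits must share the sample set and (unweighted) design; weights may
    differ per cluster.  The degrees of freedom nu is the common residual df.
    """
    if isinstance(fits, dict):
        clusters = clusters or list(fits.keys())
        fits = [fits[c] for c in clusters]
    m = len(fits)
    k = fits[0].columns.index(coef) if isinstance(coef, str) else int(coef)
    n = fits[0].Xw.shape[0]
    d = fits[0].df
    for f in fits:
        if f.Xw.shape[0] != n:
            raise ValueError("fits have mismatched sample sets")
    betas = np.array([f.beta[k] for f in fits])
    omega = np.empty((m, m))
    for i in range(m):
        fi = fits[i]
        ai = fi.xtx_inv[k, :]
        for j in range(i, m):
            fj = fits[j]
            ctilde = float(fi.resid_weighted @ fj.resid_weighted) / d
            val = ctilde * float(ai @ (fi.Xw.T @ fj.Xw) @ fj.xtx_inv[:, k])
            omega[i, j] = omega[j, i] = val
    return CoefCovariance(omega, float(d), betas, clusters or [f"c{i}" for i in range(m)])


# ---------------------------------------------------------- empirical Bayes


@dataclass
class EBPrior:
    """Scaled-inverse-chi-square prior on residual variances."""

    d0: float
    s0_squared: float


_D0_CAP = 1e6


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (trigamma is decreasing, convex)
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    # Newton on 1/trigamma(x) = 1/y, which is nearly linear in x
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x + step, 1e-12)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def eb_moderate(
    sigma2: np.ndarray, d: float | np.ndarray
) -> tuple[EBPrior, np.ndarray, np.ndarray]:
    """Shrink residual variances toward a common prior (moment matching on
    log variances).

    Returns the estimated prior, the posterior (moderated) variances
    ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the posterior df ``d0 + d`` used
    for moderated-t p-values.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if (s2 <= 0).any():
        raise ValueError("residual variances must be positive")
    m = s2.size
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if (d <= 0).any():
        raise ValueError("residual df must be positive")
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(e.mean())
    rhs = float(((e - ebar) ** 2).sum() / (m - 1) - polygamma(1, d / 2.0).mean())
    if rhs <= 0:
        d0 = _D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(rhs), _D0_CAP)
    s0_sq = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post_var = (d0 * s0_sq + d * s2) / (d0 + d)
    post_df = d0 + d
    return EBPrior(d0, s0_sq), post_var, post_df


# ------------------------------------------------------------- mixed effects


@dataclass
class LMMFit:
    """REML random-intercept fit with known precision weights."""

    beta: np.ndarray
    columns: list[str]
    Sigma: np.ndarray            # covariance of fixed effects
    sigma2: float                # residual variance (whitened scale)
    varcomp: dict[str, float]    # random-intercept variances
    resid_whitened: np.ndarray
    df: float                    # Satterthwaite-style residual df
    weights: np.ndarray
    singular: bool = False
    converged: bool = True

    @property
    def xtx_inv(self) -> np.ndarray:
        return self.Sigma / self.sigma2


def _incidence(codes: np.ndarray) -> np.ndarray:
    levels = np.unique(codes)
    return (codes[:, None] == levels[None, :]).astype(float)


def _reml_pieces(loggam: np.ndarray, Zs: list[np.ndarray], X, y, w):
    n, c = X.shape
    V0 = np.diag(1.0 / w)
    for g, Z in zip(np.exp(loggam), Zs):
        V0 += g * (Z @ Z.T)
    L = np.linalg.cholesky(V0)
    Xs = scipy.linalg.solve_triangular(L, X, lower=True)
    ys = scipy.linalg.solve_triangular(L, y, lower=True)
    XtVX = Xs.T @ Xs
    beta = np.linalg.solve(XtVX, Xs.T @ ys)
    r = ys - Xs @ beta
    quad = float(r @ r)
    s2 = quad / (n - c)
    logdetV0 = 2.0 * float(np.log(np.diag(L)).sum())
    _, logdetXtVX = np.linalg.slogdet(XtVX)
    crit = (n - c) * np.log(s2) + logdetV0 + logdetXtVX  # -2 REML ll + const
    return crit, beta, s2, XtVX, r, L


def fit_weighted_lmm(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    groups: dict[str, np.ndarray],
    w: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> LMMFit:
    """REML fit of a random-intercept model with precision weights.

    Model: y = X b + sum_k Z_k u_k + e, u_k ~ N(0, s_k^2 I),
    e_j ~ N(0, s^2 / w_j).  Variance ratios are profiled and optimized
    numerically; singular fits (a variance component at its lower bound) are
    flagged, not raised.
    """
    if isinstance(X, pd.DataFrame):
        columns = columns or list(X.columns)
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, c = X.shape
    columns = columns or [f"x{j}" for j in range(c)]
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    names = list(groups.keys())
    if not names:
        f = fit_weighted_lm(y, X, w, columns)
        return LMMFit(f.beta, columns, f.Sigma, f.sigma2, {}, f.resid_weighted,
                      f.df, w, singular=False, converged=True)
    Zs = []
    for name in names:
        codes = np.asarray(groups[name])
        if len(np.unique(codes)) < 2:
            raise ValueError(f"grouping factor {name!r} needs >= 2 levels")
        Zs.append(_incidence(codes))

    def obj(lg):
        return _reml_pieces(lg, Zs, X, y, w)[0]

    x0 = np.zeros(len(names))
    res = scipy.optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    lg = np.clip(res.x, -13.0, 13.0)
    crit, beta, s2, XtVX, r, L = _reml_pieces(lg, Zs, X, y, w)
    Sigma = s2 * np.linalg.inv(XtVX)
    varcomp = {name: s2 * float(np.exp(g)) for name, g in zip(names, lg)}
    singular = bool((lg <= -12.0).any())
    df = _satterthwaite_df(lg, s2, Zs, X, y, w, n, c)
    return LMMFit(beta, columns, Sigma, s2, varcomp, r, df, w,
                  singular=singular, converged=bool(res.success or res.fun <= crit + 1e-6))


def _satterthwaite_df(lg, s2, Zs, X, y, w, n, c, coef_index: int | None = None) -> float:
    """Satterthwaite residual df: 2 f^2 / var(f) with f the (average)
    coefficient sampling variance, var(f) from the inverse REML Hessian."""
    theta = np.concatenate([lg, [np.log(s2)]])

    def m2ll(th):
        lgam, ls2 = th[:-1], th[-1]
        crit, *_ = _reml_pieces(lgam, Zs, X, y, w)
        # un-profile sigma2: -2ll(th) up to const
        _, beta, s2p, XtVX, r, L = _reml_pieces(lgam, Zs, X, y, w)
        s2v = np.exp(ls2)
        quad = float(r @ r)
        logdetV0 = 2.0 * float(np.log(np.diag(L)).sum())
        _, logdetXtVX = np.linalg.slogdet(XtVX)
        return (n - c) * ls2 + quad / s2v + logdetV0 + logdetXtVX

    def fvar(th):
        lgam, ls2 = th[:-1], th[-1]
        _, _, _, XtVX, _, _ = _reml_pieces(lgam, Zs, X, y, w)
        C = np.exp(ls2) * np.linalg.inv(XtVX)
        if coef_index is None:
            return float(np.trace(C)) / c
        return float(C[coef_index, coef_index])

    try:
        k = theta.size
        h = 1e-4
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.eye(k)[i] * h
                ej = np.eye(k)[j] * h
                H[i, j] = H[j, i] = (
                    m2ll(theta + ei + ej) - m2ll(theta + ei - ej)
                    - m2ll(theta - ei + ej) + m2ll(theta - ei - ej)
                ) / (4 * h * h)
        A = 2.0 * np.linalg.inv(H)  # cov(theta_hat): inv of 0.5 * Hess(-2ll)
        g = np.array([
            (fvar(theta + np.eye(k)[i] * h) - fvar(theta - np.eye(k)[i] * h)) / (2 * h)
            for i in range(k)
        ])
        f0 = fvar(theta)
        denom = float(g @ A @ g)
        if denom <= 0 or not np.isfinite(denom):
            return float(n - c)
        df = 2.0 * f0 * f0 / denom
        return float(np.clip(df, 1.0, n - c))
    except np.linalg.LinAlgError:
        return float(n - c)


def _sqrtm_psd(S: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (S + S.T))
    if vals.min() < -1e-8 * max(1.0, abs(vals.max())):
        raise ValueError("covariance matrix is not positive semidefinite")
    vals = np.maximum(vals, floor)
    return (vecs * np.sqrt(vals)) @ vecs.T


def lmm_cross_covariance(fit_i: LMMFit | WLSFit, fit_j: LMMFit | WLSFit) -> np.ndarray:
    """Covariance block between two clusters' coefficient vectors:
    cor(r_i, r_j) * sqrtm(S_i) @ sqrtm(S_j)."""
    ri, rj = fit_i.resid_whitened, fit_j.resid_whitened
    if len(ri) != len(rj):
        raise ValueError("fits have mismatched sample sets")
    if fit_i is fit_j:
        return np.asarray(fit_i.Sigma, dtype=float).copy()
    # uncentered correlation: whitened residuals are orthogonal to the
    # whitened intercept, not to 1, and only the cosine makes this formula
    # collapse to the fixed-effects one under shared weights
    rho = float(ri @ rj / np.sqrt((ri @ ri) * (rj @ rj)))
    return rho * _sqrtm_psd(fit_i.Sigma) @ _sqrtm_psd(fit_j.Sigma)


# ------------------------------------------------------------------ pipeline


@dataclass
class FitResult:
    """Per-cluster fits, moderated statistics, and the machinery to build
    cross-cluster coefficient covariances."""

    clusters: list[str]
    fits: dict[str, WLSFit | LMMFit]
    design: pd.DataFrame
    coef: str
    prior: EBPrior | None
    table: pd.DataFrame
    mixed: bool

    def coef_covariance(self, clusters: list[str] | None = None) -> CoefCovariance:
        """Omega-hat of the coefficient of interest across (a subset of)
        clusters, with its degrees of freedom nu."""
        clusters = clusters or self.clusters
        fits = [self.fits[c] for c in clusters]
        if not self.mixed:
            return cross_covariance(fits, self.coef, clusters)  # type: ignore[arg-type]
        k = fits[0].columns.index(self.coef)
        m = len(fits)
        omega = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                block = lmm_cross_covariance(fits[i], fits[j])
                omega[i, j] = omega[j, i] = block[k, k]
        betas = np.array([f.beta[k] for f in fits])
        nu = float(np.median([f.df for f in fits]))
        return CoefCovariance(0.5 * (omega + omega.T), nu, betas, clusters)


def fit_composition(
    cres: CrumblrResult,
    metadata: SampleMetadata | pd.DataFrame,
    formula: str,
    coef: str,
    use_weights: bool = True,
) -> FitResult:
    """Fit the per-cluster precision-weighted model and moderate statistics.

    ``formula`` is a right-hand-side formula over metadata columns; random
    intercepts are written ``(1|group)``.  ``coef`` names the coefficient to
    test.  Set ``use_weights=False`` for the unweighted-CLR ablation.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = SampleMetadata(metadata)
    missing = [s for s in cres.sample_ids if s not in metadata.table.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = metadata.table.loc[cres.sample_ids]
    spec = ModelSpec.parse(formula, coef)
    X = spec.design(meta)
    coef_col = spec.resolve_coef(X.columns)
    groups = {
        g: meta[g].to_numpy() for g in spec.random_terms
    }
    clusters = cres.cluster_ids
    fits: dict[str, WLSFit | LMMFit] = {}
    for cl in clusters:
        y = cres.clr_values[cl].to_numpy()
        w = cres.weights[cl].to_numpy() if use_weights else None
        if groups:
            fits[cl] = fit_weighted_lmm(y, X, groups, w)
        else:
            fits[cl] = fit_weighted_lm(y, X, w)
    k = fits[clusters[0]].columns.index(coef_col)
    betas = np.array([fits[c].beta[k] for c in clusters])
    unscaled = np.array([fits[c].xtx_inv[k, k] for c in clusters])
    s2 = np.array([fits[c].sigma2 for c in clusters])
    dfs = np.array([fits[c].df for c in clusters])
    if len(clusters) >= 4:
        prior, post_var, post_df = eb_moderate(s2, dfs)
    else:
        logger.warning("fewer than 4 clusters: skipping empirical-Bayes moderation")
        prior, post_var, post_df = None, s2, dfs
    se = np.sqrt(post_var * unscaled)
    tstat = betas / se
    pval = 2.0 * t_dist.sf(np.abs(tstat), np.minimum(post_df, 1e6))
    fdr = multipletests(pval, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "cluster": clusters,
            "estimate": betas,
            "se": se,
            "t": tstat,
            "p_value": pval,
            "fdr": fdr,
        }
    ).set_index("cluster")
    return FitResult(
        clusters=list(clusters),
        fits=fits,
        design=X,
        coef=coef_col,
        prior=prior,
        table=table,
        mixed=bool(groups),
    )
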
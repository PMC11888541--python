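"""Benchmarking the weighted-CLR test against standard comparators.

Comparators fall into two families: linear models on a transformed cell
fraction (fraction, log, logit, arcsin-sqrt, unweighted CLR) and direct
count models (Poisson, negative binomial, binomial, beta-binomial).  Count
models use a log-total offset; fraction transforms reuse the pseudocount
policy of the CLR module.  Methods are scored by the area under the
precision-recall curve (AUPR) for recovering truly affected clusters and by
the false positive rate at a 5% p-value cutoff under null simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import average_precision_score

from .clr import crumblr
from .regression import eb_moderate, fit_weighted_lm
from .simulate import SimulatedDataset, SimulationConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkResult", "ALL_METHODS", "run_comparators", "score", "run_benchmark"]

ALL_METHODS = (
    "crumblr",
    "lm_fraction",
    "lm_log",
    "lm_logit",
    "lm_asin_sqrt",
    "lm_clr_unweighted",
    "poisson",
    "negative_binomial",
    "binomial",
    "betabinomial",
)


@dataclass
class BenchmarkResult:
    """Per-method AUPR and FPR over replicated simulations."""

    summary: pd.DataFrame       # method x {aupr_pooled, aupr_mean, fpr_at_5pct}
    p_tables: list[pd.DataFrame]
    n_replicates: int
    seed: int


def _design(dataset: SimulatedDataset) -> np.ndarray:
    x = dataset.metadata["x"].to_numpy(float)
    return np.column_stack([np.ones(len(x)), x])


def _crumblr_pvalues(counts, X, use_weights: bool, pseudocount: float = 0.5) -> np.ndarray:
    """Weighted-CLR pipeline p-values for the covariate (column 1 of X)."""
    cres = crumblr(counts, pseudocount=pseudocount)
    m = counts.n_clusters
    betas = np.empty(m)
    unscaled = np.empty(m)
    s2 = np.empty(m)
    for j in range(m):
        w = cres.weights.iloc[:, j].to_numpy() if use_weights else None
        f = fit_weighted_lm(cres.clr_values.iloc[:, j].to_numpy(), X, w)
        betas[j], unscaled[j], s2[j] = f.beta[1], f.xtx_inv[1, 1], f.sigma2
    d = X.shape[0] - X.shape[1]
    if m >= 4:
        _, post_var, post_df = eb_moderate(s2, float(d))
    else:
        post_var, post_df = s2, np.full(m, float(d))
    tstat = betas / np.sqrt(post_var * unscaled)
    return 2.0 * stats.t.sf(np.abs(tstat), np.minimum(post_df, 1e6))


def _lm_pvalues(y_matrix: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain OLS t-test p-values for column 1, one response per column."""
    n, c = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y_matrix
    resid = y_matrix - X @ beta
    s2 = (resid**2).sum(axis=0) / (n - c)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    tstat = beta[1] / se
    return 2.0 * stats.t.sf(np.abs(tstat), n - c)


def _glm_pvalue(endog, X, family, offset=None) -> float:
    try:
        res = sm.GLM(endog, X, family=family, offset=offset).fit()
        return float(res.pvalues[1])
    except Exception:
        return np.nan


def _negbin_pvalue(y, X, offset) -> float:
    try:
        with np.errstate(all="ignore"):
            res = sm.NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params).all():
            raise ValueError
        alpha = float(res.params[-1])
        if alpha < 1e-8:
            raise ValueError("dispersion at boundary")
        return float(res.pvalues[1])
    except Exception:
        logger.debug("negative-binomial fit failed; falling back to Poisson")
        return _glm_pvalue(y, X, sm.families.Poisson(), offset)


def _betabinom_pvalue(y, totals, X) -> float:
    """Beta-binomial regression by ML; likelihood-ratio p for the covariate."""
    frac = (y.sum() + 0.5) / (totals.sum() + 1.0)
    b0 = float(np.log(frac / (1 - frac)))

    def nll(params, null):
        if null:
            eta = params[0]
            logk = params[1]
        else:
            eta = params[0] + params[1] * X[:, 1]
            logk = params[2]
        k = np.exp(np.clip(logk, -10, 15))
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        a = np.maximum(p * k, 1e-10)
        b = np.maximum((1 - p) * k, 1e-10)
        ll = stats.betabinom.logpmf(y, totals, a, b)
        return -float(np.sum(ll))

    try:
        r0 = scipy.optimize.minimize(nll, [b0, 2.0], args=(True,), method="Nelder-Mead",
                                     options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        r1 = scipy.optimize.minimize(nll, [r0.x[0], 0.0, r0.x[1]], args=(False,),
                                     method="Nelder-Mead",
                                     options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        lrt = max(2.0 * (r0.fun - r1.fun), 0.0)
        return float(stats.chi2.sf(lrt, 1))
    except Exception:
        return np.nan


def run_comparators(
    dataset: SimulatedDataset,
    methods: tuple[str, ...] = ALL_METHODS,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """P-values of the covariate for each requested method and cluster."""
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    counts = dataset.counts
    X = _design(dataset)
    totals = counts.totals
    D = counts.n_clusters
    frac = (counts.counts + pseudocount) / (totals + D * pseudocount)[:, None]
    out = {}
    for method in methods:
        if method == "crumblr":
            out[method] = _crumblr_pvalues(counts, X, True, pseudocount)
        elif method == "lm_clr_unweighted":
            out[method] = _crumblr_pvalues(counts, X, False, pseudocount)
        elif method == "lm_fraction":
            out[method] = _lm_pvalues(frac, X)
        elif method == "lm_log":
            out[method] = _lm_pvalues(np.log(frac), X)
        elif method == "lm_logit":
            out[method] = _lm_pvalues(np.log(frac) - np.log1p(-frac), X)
        elif method == "lm_asin_sqrt":
            out[method] = _lm_pvalues(np.arcsin(np.sqrt(frac)), X)
        elif method == "poisson":
            off = np.log(totals.astype(float))
            out[method] = np.array(
                [_glm_pvalue(counts.counts[:, j], X, sm.families.Poisson(), off)
                 for j in range(D)]
            )
        elif method == "negative_binomial":
            off = np.log(totals.astype(float))
            out[method] = np.array(
                [_negbin_pvalue(counts.counts[:, j], X, off) for j in range(D)]
            )
        elif method == "binomial":
            out[method] = np.array(
                [
                    _glm_pvalue(
                        np.column_stack([counts.counts[:, j], totals - counts.counts[:, j]]),
                        X, sm.families.Binomial(),
                    )
                    for j in range(D)
                ]
            )
        elif method == "betabinomial":
            out[method] = np.array(
                [_betabinom_pvalue(counts.counts[:, j], totals, X) for j in range(D)]
            )
    return pd.DataFrame(out, index=counts.cluster_ids).T


def score(
    p_tables: list[pd.DataFrame],
    truths: list[np.ndarray],
    alpha: float = 0.05,
    null_p_tables: list[pd.DataFrame] | None = None,
) -> BenchmarkResult:
    """AUPR (pooled and replicate-averaged) and FPR at ``alpha``.

    FPR is computed on ``null_p_tables`` when given, else on the null
    clusters of ``p_tables``.
    """
    methods = list(p_tables[0].index)
    rows = {}
    for method in methods:
        scores, labels, per_rep = [], [], []
        for tab, truth in zip(p_tables, truths):
            p = tab.loc[method].to_numpy(float)
            ok = np.isfinite(p)
            if ok.sum() == 0:
                continue
            s = -np.log10(np.maximum(p[ok], 1e-300))
            t = np.asarray(truth)[ok].astype(int)
            scores.append(s)
            labels.append(t)
            if 0 < t.sum() < t.size:
                per_rep.append(average_precision_score(t, s))
        if not scores:
            logger.warning("method %s produced no finite p-values; excluded", method)
            continue
        pooled_s = np.concatenate(scores)
        pooled_t = np.concatenate(labels)
        aupr_pooled = (
            average_precision_score(pooled_t, pooled_s)
            if 0 < pooled_t.sum() < pooled_t.size
            else np.nan
        )
        fpr_source = null_p_tables if null_p_tables is not None else p_tables
        fpr_truths = (
            [np.zeros(t.shape[1], dtype=bool) for t in null_p_tables]
            if null_p_tables is not None
            else truths
        )
        null_p = []
        for tab, truth in zip(fpr_source, fpr_truths):
            p = tab.loc[method].to_numpy(float)
            nullmask = ~np.asarray(truth).astype(bool)
            null_p.append(p[nullmask & np.isfinite(p)])
        null_p = np.concatenate(null_p) if null_p else np.array([])
        fpr = float((null_p < alpha).mean()) if null_p.size else np.nan
        rows[method] = {
            "aupr_pooled": aupr_pooled,
            "aupr_mean": float(np.mean(per_rep)) if per_rep else np.nan,
            "fpr_at_5pct": fpr,
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return BenchmarkResult(summary, p_tables, len(p_tables), seed=-1)


def run_benchmark(
    config: SimulationConfig,
    methods: tuple[str, ...] = ALL_METHODS,
    n_replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> BenchmarkResult:
    """Simulate ``n_replicates`` cohorts from ``config`` and score methods."""
    p_tables, truths = [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            **{**config.__dict__, "seed": (seed + 1_000_003 * r) % 2**31}
        )
        ds = simulate(cfg)
        p_tables.append(run_comparators(ds, methods))
        truths.append(ds.truth["affected"].to_numpy())
    res = score(p_tables, truths, alpha=alpha)
    res.seed = seed
    return res
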
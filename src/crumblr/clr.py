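"""Centered log-ratio transform with Dirichlet-multinomial sampling variances.

For a composition p of D parts observed as n counts, the CLR of part i is
``log p_i - (1/D) sum_j log p_j``.  Under a Dirichlet-multinomial with
overdispersion tau, the delta method gives the asymptotic sampling variance

    var clr_i(p) = (tau/n) * [ 1/p_i - 2/(D p_i) + (1/D^2) sum_j 1/p_j ].

Reciprocals of these variances serve as precision weights in downstream
regressions.  Because coefficient estimates are invariant to a common
rescaling of the weights, tau can be fixed at 1 rather than estimated.
Weights are regularized per cluster so the largest weight is at most
``max_ratio`` times a low quantile, preventing a few high-count samples from
dominating a fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CompositionMatrix

__all__ = ["CrumblrResult", "clr_transform", "clr_variance", "regularize_weights", "crumblr"]


@dataclass
class CrumblrResult:
    """CLR values with sampling variances and regularized precision weights.

    All three tables are samples x clusters.  ``weights`` are the
    regularized reciprocal variances; their absolute scale is arbitrary
    (only ratios matter downstream).
    """

    clr_values: pd.DataFrame
    sampling_variance: pd.DataFrame
    weights: pd.DataFrame
    tau: float
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clr_values.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.clr_values.columns)


def _proportions(counts_row: np.ndarray, pseudocount: float) -> np.ndarray:
    x = np.asarray(counts_row, dtype=float) + pseudocount
    total = x.sum()
    if total <= 0:
        raise ValueError("undefined log ratio: all-zero row with pseudocount 0")
    p = x / total
    if (p <= 0).any():
        raise ValueError("zero proportion encountered; use a positive pseudocount")
    return p


def clr_transform(counts_row: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """CLR transform of one row of counts (or of proportions directly)."""
    p = _proportions(counts_row, pseudocount)
    logp = np.log(p)
    return logp - logp.mean()


def clr_variance(
    counts_row: np.ndarray, tau: float = 1.0, pseudocount: float = 0.5
) -> np.ndarray:
    """Delta-method sampling variance of the CLR under the Dirichlet-multinomial.

    The plug-in proportions use the pseudocount-adjusted row; the total n is
    the raw count total (pseudocounts are a continuity device, not
    observations).
    """
    raw = np.asarray(counts_row, dtype=float)
    n = raw.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    p = _proportions(raw, pseudocount)
    D = p.size
    inv = 1.0 / p
    return (tau / n) * (inv - 2.0 * inv / D + inv.sum() / D**2)


def regularize_weights(
    weights: np.ndarray, max_ratio: float = 5.0, quantile: float = 0.05
) -> np.ndarray:
    """Clip weights so max(w) / quantile(w, q) <= max_ratio.

    Applied per cluster across samples.  Weights at or below the quantile
    reference are untouched; larger ones are capped at ``max_ratio`` times it.
    Clipping lowers the quantile slightly, so the cap is re-applied until the
    ratio bound actually holds (one pass suffices for all but tiny vectors).
    """
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    for _ in range(100):
        q = np.quantile(w, quantile)
        if w.max() <= max_ratio * q * (1 + 1e-12):
            break
        w = np.minimum(w, max_ratio * q)
    return w


def crumblr(
    counts: CompositionMatrix | pd.DataFrame,
    tau: float = 1.0,
    pseudocount: float = 0.5,
    max_ratio: float = 5.0,
    quantile: float = 0.05,
) -> CrumblrResult:
    """CLR-transform a count matrix and attach variances and precision weights.

    Parameters
    ----------
    counts
        Samples x clusters cell counts.
    tau
        Overdispersion used in the variance formula.  Downstream regression
        results are invariant to tau (it rescales all weights), so the
        default of 1 is safe even for overdispersed data.
    pseudocount
        Added to every count before forming proportions; guarantees finite
        log-ratios with zero counts.  Set 0 to disable.
    max_ratio, quantile
        Weight-regularization parameters: per cluster, weights are capped at
        ``max_ratio`` times the ``quantile`` sample quantile.
    """
    if isinstance(counts, pd.DataFrame):
        counts = CompositionMatrix.from_dataframe(counts)
    if counts.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    totals = counts.totals
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    # vectorized row-wise transform + variance (same math as clr_transform /
    # clr_variance, which stay as the scalar reference path)
    x = counts.counts.astype(float) + pseudocount
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("undefined log ratio: all-zero row with pseudocount 0")
    if (x <= 0).any():
        raise ValueError("zero proportion encountered; use a positive pseudocount")
    p = x / x.sum(axis=1, keepdims=True)
    logp = np.log(p)
    clr = logp - logp.mean(axis=1, keepdims=True)
    D = counts.n_clusters
    inv = 1.0 / p
    var = (tau / totals.astype(float))[:, None] * (
        inv - 2.0 * inv / D + inv.sum(axis=1, keepdims=True) / D**2
    )
    w = 1.0 / var
    w = np.column_stack(
        [regularize_weights(w[:, j], max_ratio, quantile) for j in range(w.shape[1])]
    )
    idx, cols = counts.sample_ids, counts.cluster_ids
    return CrumblrResult(
        clr_values=pd.DataFrame(clr, index=idx, columns=cols),
        sampling_variance=pd.DataFrame(var, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        tau=float(tau),
        pseudocount=float(pseudocount),
    )
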
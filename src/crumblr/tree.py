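"""Hypothesis testing along a cell-lineage hierarchy.

Leaves report the univariate moderated test of their cluster.  Each internal
node reports a Lin-Sullivan multivariate test over the coefficient vector of
all its descendant-leaf clusters, with the cross-cluster covariance taken
from the fitted models.  FDR is controlled jointly over leaves and internal
nodes with Benjamini-Hochberg.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import ClusterTree
from .mvtest import empirical_null, lin_sullivan, ls_empirical_pvalue
from .regression import FitResult

__all__ = ["TreeTestResult", "test_tree", "fdr_adjust"]


@dataclass
class TreeTestResult:
    """Per-node effect estimates, statistics and FDR across a hierarchy."""

    table: pd.DataFrame  # node, is_leaf, n_leaves, estimate, statistic, p_value, fdr

    def node(self, node_id: str) -> pd.Series:
        return self.table.loc[node_id]


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_tree(
    fit: FitResult,
    tree: ClusterTree,
    null_method: str = "auto",
    n_draws: int = 10000,
    seed: int = 0,
    ridge: bool = True,
) -> TreeTestResult:
    """Test every node of a cluster hierarchy for differential composition.

    Parameters
    ----------
    fit
        Result of :func:`crumblr.fit_composition`; its coefficient of
        interest is the quantity tested.
    null_method
        ``asymptotic`` (chi-square 1 df), ``empirical`` (Wishart Monte-Carlo
        null), or ``auto`` (empirical when the residual df is below 50 times
        the node size, i.e. in small-sample settings).
    """
    if null_method not in {"auto", "asymptotic", "empirical"}:
        raise ValueError(f"unknown null_method {null_method!r}")
    tree.validate_against(fit.clusters)
    rows = []
    for leaf in tree.leaf_labels:
        r = fit.table.loc[leaf]
        rows.append(
            dict(node=leaf, is_leaf=True, n_leaves=1, estimate=r["estimate"],
                 statistic=r["t"], p_value=r["p_value"])
        )
    for node_id, members in tree.internal_nodes():
        if len(members) == 1:
            r = fit.table.loc[members[0]]
            rows.append(
                dict(node=node_id, is_leaf=False, n_leaves=1, estimate=r["estimate"],
                     statistic=r["t"], p_value=r["p_value"])
            )
            continue
        cov = fit.coef_covariance(members)
        m = len(members)
        use_empirical = null_method == "empirical" or (
            null_method == "auto" and cov.nu < 50 * m
        )
        if use_empirical and cov.nu >= m:
            node_seed = (seed + zlib.crc32(node_id.encode()) % 100000) % (2**31)
            res = ls_empirical_pvalue(
                cov.betas, cov.omega, cov.nu, n_draws=n_draws,
                seed=node_seed, ridge=ridge,
            )
        else:
            res = lin_sullivan(cov.betas, cov.omega, ridge=ridge)
        rows.append(
            dict(node=node_id, is_leaf=False, n_leaves=m,
                 estimate=res.combined_effect, statistic=res.statistic,
                 p_value=res.p_value)
        )
    table = pd.DataFrame(rows).set_index("node")
    table["fdr"] = fdr_adjust(table["p_value"].to_numpy())
    return TreeTestResult(table)
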
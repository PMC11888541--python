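"""Variance partitioning of CLR-transformed cell-type frequencies.

For each cluster, a precision-weighted random-intercept model is fitted with
every categorical metadata variable as a random intercept and every numeric
variable as a fixed effect.  The fraction attributed to a categorical
variable is its variance component; for a numeric variable it is the sample
variance of its fitted contribution X_k * beta_k; the residual picks up the
rest.  Fractions are normalized to sum to one per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clr import CrumblrResult
from .data_model import SampleMetadata
from .regression import fit_weighted_lmm

logger = logging.getLogger(__name__)

__all__ = ["VariancePartitionResult", "partition_variance"]


@dataclass
class VariancePartitionResult:
    """Clusters x (variables + residual) matrix of variance fractions in [0, 1]."""

    fractions: pd.DataFrame
    singular: dict[str, bool]


def partition_variance(
    cres: CrumblrResult,
    metadata: SampleMetadata | pd.DataFrame,
    variables: list[str],
) -> VariancePartitionResult:
    """Fraction of each cluster's CLR variance explained by each variable."""
    if isinstance(metadata, pd.DataFrame):
        metadata = SampleMetadata(metadata)
    meta = metadata.table.loc[cres.sample_ids]
    categorical = [v for v in variables if not pd.api.types.is_numeric_dtype(meta[v])]
    numeric = [v for v in variables if v in set(variables) - set(categorical)]
    for v in categorical:
        if meta[v].nunique() < 2:
            raise ValueError(f"categorical variable {v!r} needs >= 2 levels")
    n = len(meta)
    if n <= len(variables) + 2:
        raise ValueError("too few samples for the number of variables")
    X = np.column_stack([np.ones(n)] + [pd.to_numeric(meta[v]).to_numpy(float) for v in numeric])
    columns = ["Intercept"] + numeric
    groups = {v: meta[v].to_numpy() for v in categorical}
    rows = {}
    singular = {}
    for cl in cres.cluster_ids:
        y = cres.clr_values[cl].to_numpy()
        w = cres.weights[cl].to_numpy()
        fit = fit_weighted_lmm(y, X, groups, w, columns=columns)
        singular[cl] = fit.singular
        if fit.singular:
            logger.warning("singular variance-component fit for cluster %s", cl)
        parts = {}
        for v in categorical:
            parts[v] = fit.varcomp.get(v, 0.0)
        for v in numeric:
            k = columns.index(v)
            contrib = X[:, k] * fit.beta[k]
            parts[v] = float(np.var(contrib, ddof=1))
        # residual variance on the observation scale; mean(1/w) makes it
        # invariant to the arbitrary overall scale of the weights
        parts["residual"] = fit.sigma2 * float(np.mean(1.0 / w))
        total = sum(parts.values())
        rows[cl] = {k: v / total for k, v in parts.items()}
    fractions = pd.DataFrame.from_dict(rows, orient="index")
    fractions = fractions[[*variables, "residual"]]
    return VariancePartitionResult(fractions, singular)
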
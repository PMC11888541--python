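"""Dirichlet-multinomial simulation of cell-cluster count cohorts.

The generator draws, per sample, a composition from a Dirichlet centered on
baseline proportions whose log-concentrations are shifted by a covariate
effect on designated clusters (and optionally by batch effects), then draws
counts from a multinomial.  The Dirichlet precision is chosen so the
proportion covariance equals (tau/n) * (diag(p) - p p'), i.e. the simulator's
overdispersion tau is exactly the tau of the CLR variance formula.

Defaults mirror the baseline study conditions used throughout the package's
power and calibration experiments: 200 samples, 10 clusters, one affected
cluster with effect size 0.2 per unit of a standard-normal covariate, a mean
of 2000 cells per sample, overdispersion 10, and no batch effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CompositionMatrix

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "simulate_multivariate"]


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_clusters: int = 10
    effect_size: float = 0.2
    affected_clusters: tuple[int, ...] = (0,)
    mean_total_counts: int = 2000
    total_counts_distribution: str = "fixed"  # "fixed", "poisson" or "lognormal"
    total_counts_cv: float = 1.0  # coefficient of variation for lognormal totals
    tau: float = 10.0
    batch_count: int = 0
    batch_variance_fraction: float = 0.0
    baseline_proportions: np.ndarray | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.total_counts_distribution not in {"fixed", "poisson", "lognormal"}:
            raise ValueError(
                "total_counts_distribution must be 'fixed', 'poisson' or 'lognormal'"
            )
        if not all(0 <= j < self.n_clusters for j in self.affected_clusters):
            raise ValueError("affected cluster index out of range")
        if isinstance(self.baseline_proportions, str):
            if self.baseline_proportions != "random":
                raise ValueError("baseline_proportions must be a vector or 'random'")
        else:
            p = np.asarray(self.baseline_proportions, dtype=float)
            if (p <= 0).any():
                raise ValueError("baseline proportions must be positive")
            self.baseline_proportions = p / p.sum()


@dataclass
class SimulatedDataset:
    counts: CompositionMatrix
    metadata: pd.DataFrame  # covariate x, optional batch
    truth: pd.DataFrame     # cluster, affected, effect
    config: SimulationConfig = field(repr=False, default=None)


def _baseline(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.baseline_proportions, str):
        # moderately uneven frequencies, occasional rare clusters
        return rng.dirichlet(np.full(config.n_clusters, 2.0))
    return np.asarray(config.baseline_proportions, dtype=float)


def _dm_counts(
    P: np.ndarray, totals: np.ndarray, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts from Multinomial(totals, Dirichlet(P*s)) with s set so the
    proportion covariance is (tau/n)(diag p - pp')."""
    n_samples = P.shape[0]
    if tau > 1:
        s = (totals.astype(float) - tau) / (tau - 1.0)
        if (s <= 0).any():
            raise ValueError("tau must be smaller than every total count")
        g = rng.standard_gamma(P * s[:, None])
        zero = g.sum(axis=1) == 0
        if zero.any():
            g[zero] = P[zero]
        P = g / g.sum(axis=1, keepdims=True)
    counts = np.empty(P.shape, dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(totals[i], P[i])
    return counts


def _batch_sd(config: SimulationConfig, baseline: np.ndarray, seed: int) -> float:
    """Pilot-calibrate the per-(batch, cluster) log-concentration shift SD so
    batch explains the requested fraction of CLR variance."""
    f = config.batch_variance_fraction
    if f <= 0 or config.batch_count <= 0:
        return 0.0
    pilot = SimulationConfig(
        n_samples=min(config.n_samples, 200),
        n_clusters=config.n_clusters,
        effect_size=0.0,
        mean_total_counts=config.mean_total_counts,
        total_counts_distribution="fixed",
        tau=config.tau,
        baseline_proportions=baseline,
        seed=seed,
    )
    from .clr import crumblr as _crumblr

    ds = simulate(pilot)
    v0 = float(_crumblr(ds.counts).clr_values.var(axis=0).mean())
    D = config.n_clusters
    # an independent shift per cluster perturbs CLR with variance (1-1/D) sd^2
    return float(np.sqrt(f / (1.0 - f) * v0 / (1.0 - 1.0 / D)))


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort of counts, covariates and ground truth."""
    rng = np.random.default_rng(config.seed)
    baseline = _baseline(config, rng)
    if baseline.size != config.n_clusters:
        raise ValueError("baseline proportion length must equal n_clusters")
    n, D = config.n_samples, config.n_clusters
    x = rng.standard_normal(n)
    loga = np.tile(np.log(baseline), (n, 1))
    effect = np.zeros(D)
    effect[list(config.affected_clusters)] = config.effect_size
    loga += x[:, None] * effect[None, :]
    meta = pd.DataFrame({"x": x}, index=[f"s{i+1}" for i in range(n)])
    if config.batch_count > 0:
        batch = rng.integers(config.batch_count, size=n)
        sd = _batch_sd(config, baseline, seed=(config.seed + 7919) % 2**31)
        shifts = rng.normal(0.0, sd, size=(config.batch_count, D)) if sd > 0 else np.zeros((config.batch_count, D))
        loga += shifts[batch]
        meta["batch"] = pd.Categorical([f"b{b+1}" for b in batch])
    P = np.exp(loga - loga.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    if config.total_counts_distribution == "poisson":
        totals = np.maximum(rng.poisson(config.mean_total_counts, size=n), 1)
    elif config.total_counts_distribution == "lognormal":
        # per-sample cell yields commonly spread over an order of magnitude;
        # lognormal with the requested CV, mean preserved
        sig = np.sqrt(np.log1p(config.total_counts_cv**2))
        draw = np.exp(rng.normal(-0.5 * sig**2, sig, size=n))
        floor = max(int(2 * config.tau), 10)
        totals = np.maximum((config.mean_total_counts * draw).astype(np.int64), floor)
    else:
        totals = np.full(n, config.mean_total_counts, dtype=np.int64)
    counts = _dm_counts(P, totals, config.tau, rng)
    cluster_ids = [f"C{j+1}" for j in range(D)]
    cm = CompositionMatrix(counts, list(meta.index), cluster_ids)
    truth = pd.DataFrame(
        {
            "cluster": cluster_ids,
            "affected": effect != 0,
            "effect": effect,
        }
    ).set_index("cluster")
    return SimulatedDataset(cm, meta, truth, config)


def simulate_multivariate(
    n: int,
    m: int,
    effect: float = 0.25,
    ratio_lambda: float = 100.0,
    alternative: bool = True,
    seed: int = 0,
    sigma: np.ndarray | None = None,
):
    """Multivariate-regression responses for testing effect combiners.

    Design is an intercept plus a standard-normal covariate.  Under the
    alternative every response carries the shared ``effect``; errors are
    multivariate normal with a random positive-definite covariance with
    eigenvalues uniform on [1, ratio_lambda] under a random rotation.

    Returns ``(X, Y, truth, sigma)``.
    """
    if m < 2:
        raise ValueError("need at least 2 responses")
    rng = np.random.default_rng(seed)
    if sigma is None:
        lam = rng.uniform(1.0, ratio_lambda, size=m)
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        sigma = (Q * lam) @ Q.T
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    L = np.linalg.cholesky(sigma)
    E = rng.standard_normal((n, m)) @ L.T
    Y = E + (effect * x[:, None] if alternative else 0.0)
    return X, Y, bool(alternative) and effect != 0, sigma
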
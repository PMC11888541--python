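import numpy as np
import pytest
from hypothesis import settings

from crumblr import CompositionMatrix, SimulationConfig, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def dirichlet_multinomial_draws(
    p: np.ndarray, n_total: int, tau: float, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Dirichlet-multinomial count draws, written directly against
    numpy primitives (test-side oracle, not the package's sampler).

    The Dirichlet precision s solves tau = (n + s) / (1 + s) so the
    proportion covariance is (tau/n) (diag p - p p')."""
    p = np.asarray(p, dtype=float)
    if tau > 1:
        s = (n_total - tau) / (tau - 1.0)
        P = rng.dirichlet(p * s, size=n_draws)
    else:
        P = np.tile(p, (n_draws, 1))
    out = np.empty((n_draws, p.size), dtype=np.int64)
    for i in range(n_draws):
        out[i] = rng.multinomial(n_total, P[i])
    return out


@pytest.fixture
def small_counts() -> CompositionMatrix:
    return CompositionMatrix(
        np.array([[5, 3, 2], [1, 0, 4]]), ["s1", "s2"], ["A", "B", "C"]
    )


@pytest.fixture
def baseline_dataset():
    return simulate(SimulationConfig(seed=42))
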
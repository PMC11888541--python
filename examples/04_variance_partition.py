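"""Variance partitioning of CLR-transformed cell frequencies.

Simulates a cohort with a batch structure engineered to explain ~30% of
the CLR variance, then attributes each cluster's variance to the covariate,
the batch, and residual noise with a precision-weighted random-effects model.
"""

from crumblr import SimulationConfig, crumblr, partition_variance, simulate

ds = simulate(
    SimulationConfig(
        n_samples=150, n_clusters=6, batch_count=8, batch_variance_fraction=0.3, seed=2
    )
)
cres = crumblr(ds.counts)
vp = partition_variance(cres, ds.metadata, ["x", "batch"])
print("Variance fractions (rows sum to 1):")
print(vp.fractions.round(3).to_string())
print(
    "\nThe batch column should sit near the requested 0.3; the covariate "
    "explains appreciable variance only in the affected cluster C1."
)
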
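"""Differential cell-type composition with precision-weighted regression.

Simulates a 200-donor cohort in which one of ten clusters shifts with a
standard-normal covariate (effect 0.2 on the log-concentration scale),
runs the weighted-CLR pipeline, and prints the moderated per-cluster tests.
"""

from crumblr import SimulationConfig, crumblr, fit_composition, simulate

ds = simulate(SimulationConfig(seed=1))
print("Truly affected cluster(s):",
      ", ".join(ds.truth.index[ds.truth["affected"]]))

cres = crumblr(ds.counts)
fit = fit_composition(cres, ds.metadata, "~ x", coef="x")
print("\nPer-cluster moderated tests (estimate is on the CLR scale):")
print(fit.table.round(4).to_string())
print(
    "\nThe affected cluster should carry a positive estimate near 0.2 and an "
    "FDR far below 0.05.  Because compositions are closed, the shift in C1 "
    "pushes the remaining clusters slightly negative."
)
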
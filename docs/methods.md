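# Methods

## The problem

Single-cell assays report, for each sample, how many cells fall in each of D
clusters.  Only the relative composition is informative (totals reflect
assay yield, not biology), and the precision of a measured frequency varies
enormously: 1000/5000 cells and 1/5 cells give the same fraction with very
different uncertainty.  This package tests for changes in composition across
samples while modeling that varying precision.

## Model

**Transform.**  Counts are converted to proportions (after adding a
pseudocount, default 0.5, to every count) and mapped through the centered
log-ratio,

    clr_i(p) = log p_i − (1/D) Σ_j log p_j ,

which removes the compositional constraint and yields approximately Gaussian,
zero-sum responses.

**Sampling variance.**  Treating the observed proportions as
Dirichlet-multinomial with total n and overdispersion τ (τ = 1 is the
multinomial), the delta method gives

    var clr_i(p) = (τ/n) [ 1/p_i − 2/(D p_i) + (1/D²) Σ_j 1/p_j ] .

Its reciprocal is the precision weight of that observation.  Because
regression coefficients and their covariance are invariant to a common
rescaling of all weights, τ never needs to be estimated; the default τ = 1
is used even for overdispersed data.

**Weight regularization.**  Raw weights can span orders of magnitude and let
a few high-count samples dominate.  Per cluster, weights are capped at
`max_ratio` (default 5) times the `quantile` (default 5%) sample quantile;
the cap is iterated to a fixed point so the stated ratio bound actually
holds on the output.

**Per-cluster inference.**  Each cluster's CLR values are fitted by weighted
least squares (or weighted REML for formulas with `(1|group)` random
intercepts).  Residual variances are shrunk across clusters by an
inverse-gamma empirical-Bayes prior estimated by moment matching on log
variances (Smyth-style; the prior df is capped at 1e6 to represent
"infinite"), giving moderated t-statistics with d0 + d degrees of freedom.
Benjamini–Hochberg FDR is reported across clusters.

**Cross-cluster covariance.**  For the multivariate test, the covariance of
one coefficient's estimates across clusters i, j uses the weighted
multivariate-regression form cov(b_i, b_j) = (r̃_i'r̃_j/d)·
(X̃_i'X̃_i)⁻¹X̃_i'X̃_j(X̃_j'X̃_j)⁻¹ with tilded quantities scaled by
√weights (so X̃'X̃ = X'WX, the only convention under which the printed
estimator is the WLS minimizer).  With equal weights this collapses to
cov(vec(B)) = cov(R) ⊗ (X'X)⁻¹.  For mixed models the block is
cor(r̃_i, r̃_j)·sqrtm(Σ_i)·sqrtm(Σ_j), where the residual correlation is the
*uncentered* cosine of the whitened residuals — residuals are orthogonal to
the weighted intercept, not to 1, and only the cosine makes this formula
coincide with the fixed-effects one when weights are shared across clusters.
Matrix square roots use a symmetric eigendecomposition with eigenvalue
floor 1e−12.

**Multivariate combination.**  Given coefficient estimates B over m clusters
with covariance Ω, the correlated fixed-effects meta-analysis statistic

    T = (1'Ω⁻¹B)² / (1'Ω⁻¹1)

is asymptotically χ²(1); the combined effect is (1'Ω⁻¹B)/(1'Ω⁻¹1).  With
diagonal Ω this is classical inverse-variance meta-analysis.  Near-singular
Ω (highly correlated sibling clusters) can be stabilized by an optional
ridge of 1e−8·mean(diag Ω).

**Finite-sample null.**  When Ω is estimated from few residual df ν, T is
far heavier-tailed than χ²(1) (inverting a noisy covariance inflates the
quadratic form).  The Monte-Carlo null draws V ~ Wishart(Ω/ν, ν) — a
plausible covariance *estimate*, E[V] = Ω — and b ~ N(0, Ω) — null
coefficients — and records T(b, V).  A two-parameter gamma is fitted to the
draws by maximum likelihood (moment start and fallback), and the observed
statistic's p-value is the gamma tail.  Note the statistic must be computed
against a covariance *other than* the one b was drawn from: T(b, V) with
b ~ N(0, V) is exactly χ²(1) for every V and carries no finite-sample
information.  At large ν the fitted gamma converges to Gamma(1/2, 2) =
χ²(1), so the empirical p-value agrees with the asymptotic one.

**Tree testing.**  Leaves of a cluster hierarchy report their univariate
moderated test.  Each internal node reports the meta-analytic test over all
its *descendant leaves* (not just immediate children, so every node is a
test on observed clusters).  The null is asymptotic when ν ≥ 50·m and the
Monte-Carlo gamma otherwise (`auto`), and FDR is controlled jointly over
all nodes.

**Variance partitioning.**  Per cluster, a precision-weighted
random-intercept model with categorical variables as random intercepts and
numeric variables as fixed effects attributes variance to each term:
variance components for categoricals, the sample variance of X_k·β̂_k for
numeric terms, and σ̂²·mean(1/w) for the residual (the mean(1/w) factor
keeps the partition invariant to the arbitrary overall weight scale).
Fractions are normalized to sum to one.

## Mixed-model machinery

statsmodels' MixedLM has no per-observation precision weights, so the REML
fit is implemented directly: with V₀(γ) = diag(1/w) + Σ_k γ_k Z_k Z_k', β
and σ² are profiled out and the variance ratios γ are optimized by
Nelder–Mead on the profiled REML criterion (log-γ bounded at ±13; a ratio at
the lower bound flags the fit singular rather than raising).  At unit
weights the fixed effects agree with statsmodels MixedLM to ~1e−5 (checked
in the tests).  A Satterthwaite-style residual df for the empirical-Bayes
step is computed as 2f²/var(f), with f the coefficient sampling variance,
its gradient by central differences in (log γ, log σ²), and var(f) from the
inverse finite-difference REML Hessian; failures fall back to n − c, and the
result is clipped to [1, n − c].

## Synthetic cohorts

The simulator draws, per sample: a standard-normal covariate x; per-cluster
log-concentrations log α_j = log(baseline_j) + effect·x·1[j affected]
(+ batch shift); a composition from a Dirichlet with precision s solving
τ = (n + s)/(1 + s), so the proportion covariance is exactly
(τ/n)(diag p − pp'); and counts from a multinomial.  Defaults are the
baseline study conditions used throughout the validation suite: 200 samples,
10 clusters, one affected cluster with effect 0.2, 2000 cells per sample,
τ = 10, no batch.  Baseline proportions default to a single Dirichlet(2)
draw per cohort — moderately uneven, with occasional rare clusters, as in
real annotations.  Batch effects are additive shifts on log-concentrations
whose SD is calibrated by a pilot simulation so batch explains the requested
fraction of CLR variance.  Totals can be fixed, Poisson, or lognormal with a
chosen CV (default 1) — the lognormal option reflects the order-of-magnitude
spread of per-sample cell yields in real studies.

The multivariate-testing simulator generates m correlated Gaussian responses
with a shared effect (default 0.25) and an error covariance with eigenvalues
uniform on [1, 100] under a random rotation (condition-number spread of
100).

What the generator does *not* emulate: cell-level structure (doublets,
ambient contamination), per-cluster overdispersion differences, covariate
effects on the total yield, or annotation error.  Passing tests therefore
demonstrate the statistical machinery under the stated generative model,
not robustness to those artifacts.

## Validation design and problem sizes

The validation suite recomputes: the null false-positive rate of the full
pipeline over 2000 simulated null cohorts (FPR ≈ 5.1–5.3%, within three
binomial SEs of nominal); χ²(1) calibration of the combined statistic at
known covariance (10⁴ draws) and the finite-sample null's FPR at ν = m + 2,
m = 15 (5000 replicates, 1000 Monte-Carlo draws each; FPR ≈ 0.033–0.05);
exact agreement of the estimators with independent oracles (numerical
minimizer, Kronecker form, classical meta-analysis); power orderings
(weighted beats unweighted CLR and fraction regression under heterogeneous
totals, the combined test beats Šidák at m = 15, and Poisson's FPR exceeds
0.10 under the overdispersed null); and recovery of the empirical-Bayes
prior (d0 = 4, s0² = 2 from 500 variances) and a 0.5 intraclass correlation
(REML, 100 replicates).  Monte-Carlo sizes are chosen so the whole suite
runs in a few minutes on one core while keeping binomial noise well inside
each asserted band.

## Known limitations

- **Delta-method variance at low concentration.**  The variance formula is
  asymptotic in n with the Dirichlet precision s = (n − τ)/(τ − 1) growing
  with n.  Its accuracy is governed by the per-component concentration
  α_j = p_j·s, *not* by the expected count alone: for α ≳ 3 the analytic SD
  tracks the empirical SD of simulated CLR values within ~10%, but as
  α → 1 the true log-scale variance (trigamma(α)) exceeds the delta
  approximation (1/α), while the pseudocount truncates the empirical spread
  — errors of 2–4× in either direction at α ≪ 1 (at τ = 10, n = 500 this
  means expected counts below ~27).  Rare components also leak error into
  every cluster through the shared geometric-mean term.  One validation
  test asserts the stricter historical claim (10% down to expected count 2
  at τ = 10, n = 500, D = 15) and fails by design, documenting the
  approximation's real domain.  Weight regularization caps the practical
  impact on inference, and the null calibration of the full pipeline holds
  (FPR ≈ 5%) even with rare clusters present.
- **When weighting helps.**  With identical totals across samples the true
  sampling variances are equal within a cluster, ordinary least squares is
  already efficient, and estimated weights merely add response-correlated
  noise — the weighted test then has no power advantage.  The benefit
  appears exactly when per-sample totals (or frequencies) vary widely,
  which the lognormal-totals simulations exercise.
- **Effect-size scale.**  Simulated effects act on log-concentrations of
  affected clusters (compositional closure renormalizes the rest), so
  power values are comparable across methods and conditions, not across
  other effect-size conventions.
- The beta-binomial comparator uses a likelihood-ratio test from a custom
  ML fit; the negative binomial falls back to Poisson when its dispersion
  estimate degenerates (logged).
- Mixed-model support covers random intercepts only; no random slopes,
  nested/crossed beyond independent factors, or non-Gaussian responses.
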
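# Methods

## Model and procedure

`dnlc` detects genes around which local expression consistency on a
biological network changes with a clinical outcome.  The procedure has
four stages.

**1. Normal-score transform.**  Each gene row of the expression matrix
(p genes × N samples) is replaced by van der Waerden scores
Φ⁻¹(r/(N+1)), where r is the within-row rank (average ranks for ties).
This makes every gene marginally Gaussian and invariant to any strictly
monotone distortion of its measurement scale.  A constant row is a hard
error — a gene with no variation cannot be ranked, and silently
imputing a value would fabricate signal.

**2. Local Moran's I (LMI).**  For gene *i* in sample *k*,

I_ik = (z_ik − z̄_k)/σ_k² · Σ_{j≠i} w_ij (z_jk − z̄_k),

with weights w_ij ∝ exp(−d_ij²/2) for hop distance d_ij ≤ radius
(default 2) and 0 beyond, row-normalized to sum to 1.  Conventions the
formula leaves open were fixed as follows:

- σ_k² is the *population* variance (divide by p) over all genes in
  sample k, and the moments include gene *i* itself.  With these
  choices the per-sample identity Σ_i I_ik = p·I_global,k (global
  Moran's I under the same weights) holds exactly, matching the
  standard definition of the statistic in spatial analysis; both
  choices are asserted by tests.
- The Gaussian kernel's 1/√(2π) constant cancels in row normalization;
  it is kept so the raw kernel is the standard normal density.
- Genes with no neighbor within the radius are retained with I ≡ 0 and
  flagged; they are excluded from downstream testing (their statistic
  would be undefined, not null) and reported in a sidecar table.
- The hop radius is exposed as a parameter (default 2) for sensitivity
  analysis; distances are unweighted hop counts computed by truncated
  breadth-first search, near-linear on sparse graphs.

**3. Outcome association.**  Each gene's LMI profile enters a
generalized linear model E(y | LMI, C) = g⁻¹(α·LMI + Σβ_m C_m):
ordinary least squares for continuous outcomes (t statistic), logistic
regression for binary (Wald z), Cox proportional hazards for survival.
Ties in the Cox partial likelihood use the Efron approximation — more
accurate than Breslow at negligible cost.  Confounders are always
included; categorical ones are one-hot encoded against a reference
level.  Genes whose model does not converge (complete separation,
monotone likelihood) or whose LMI row is constant are marked untestable
with a reason code.

**4. Empirical-null lfdr.**  The pooled Wald statistics are modelled as
f(t) = π₀f₀(t) + (1−π₀)f₁(t).  The marginal f is estimated by Poisson
regression of histogram counts (120 bins spanning the data) on a cubic
B-spline basis with 7 degrees of freedom; the empirical null
f₀ = Normal(δ₀, σ₀) is fitted by central matching — a quadratic fit to
log f over the central 50% of the distribution — with
σ₀ = √(−1/(2c₂)), δ₀ = −c₁/(2c₂), and π₀ = f(δ₀)·σ₀√(2π) clipped to
(0, 1].  Per-gene lfdr = clip(π₀f₀(t)/f(t), 0, 1); genes with
lfdr ≤ 0.2 (default threshold) are DC genes, split into positive and
negative by the sign of their statistic.

When the non-null fraction is so large that the pooled distribution
becomes multimodal, the log density is not concave near its center and
central matching has no solution; the fit then falls back, with a
logged warning, to the theoretical N(0, 1) null (Wald statistics are
asymptotically standard normal gene-wise under the null) with π₀
matched to the marginal at zero.  This keeps the ranking of genes
usable far outside the sparse-signal regime the empirical null assumes.
Fewer than 200 finite statistics is an error: density estimation on
tiny panels is unreliable and single-gene methods should be used
instead.

**Community stage.**  DC genes plus their direct neighbors induce a
subgraph; fast-greedy (Clauset–Newman–Moore) modularity maximization
partitions it into communities, deterministic for a fixed input.  An
edgeless subgraph yields singleton communities with modularity 0.
Gene-set over-representation per community uses the exact
hypergeometric upper tail with BH adjustment across sets within each
community.  The universe defaults to all *tested* genes — conditioning
on what the selection could have picked — and community members outside
the universe (e.g. untestable neighbors) are excluded from the overlap
counts.  Gene sets are supplied as GMT files; no ontology structure is
assumed.

## Synthetic data generator

The generator emulates a cohort in which network-local co-expression —
not expression level — differs between two conditions:

1. Barabási–Albert scale-free network, m nodes (default 500),
   2 edges per arriving node.  The attachment count is not a quantity
   with an obvious biological anchor; 2 gives mean degree ≈ 4,
   comparable to sparse curated interactomes, while still populating
   degree ranges 5–10 and 15–20 for center eligibility at m ≥ 500.
2. Covariance Σ_ij = c^{d_ij} with d the shortest-path distance; the
   base correlation c defaults to 0.2.
3. Five centers drawn uniformly among nodes with degree in a configured
   range (default 5–10); inside the union P of their closed 2-hop
   neighborhoods the covariance is rewritten to b^{d_ij} (changed
   correlation, default 0.8) for pairs with *both* endpoints in P.
   Cross pairs (one endpoint inside) keep base entries by default — a
   flag includes them for sensitivity analysis.  Ground truth marks all
   of P: every node in P has changed correlation with neighbors, not
   only the centers.
4. n samples from MVN(0, Σ) and n from MVN(0, Σ′) are joined into an
   m × 2n matrix; the outcome is 0 for the first block, 1 for the
   second.

c^d on an arbitrary graph need not be positive semidefinite, so both
covariances are repaired by eigenvalue clipping at 1e-8 followed by
rescaling to unit diagonal; the Frobenius norm of the repair is logged.
Sampling factorizes each covariance once by symmetric eigendecomposition.

What the generator does *not* emulate: measurement noise models
(counts, dropout), mean shifts confounded with consistency changes,
edge weights or directionality, or realistic interactome topology
beyond scale-freeness.  Passing benchmarks therefore show the method
recovers *correlation-structure* perturbations planted on a scale-free
graph — they do not certify performance on a specific real interactome.

A structural note at desk scale: with m = 500 and attachment 2, hubs
are reachable within two hops from much of the graph, so the perturbed
set P typically covers 30–50% of nodes and the PR-AUC prevalence floor
is correspondingly high.  This is why benchmark results are always read
against the per-replicate prevalence rather than against zero.

## Benchmark

Per replicate (independently seeded from the configuration seed), the
full pipeline (weights → LMI → logistic association → lfdr) and a
differential-expression baseline (per-gene pooled-variance two-sample
t-test on raw expression, statistics fed to the same lfdr machinery)
are scored by the area under the precision–recall curve, using per-gene
lfdr as the predictor (lower = more confidently perturbed).  PR-AUC
uses the step-interpolation (average-precision) rule, which avoids the
optimism of trapezoidal interpolation; ties are grouped at a single
threshold, so constant scores score exactly the prevalence.  Untestable
genes receive lfdr 1 so every node is ranked.  A failed replicate is
recorded and skipped rather than aborting the run.  The harness accepts
external per-gene score files so third-party methods can be compared on
the same replicates.

Default problem sizes (500 genes, 5 replicates, n ≤ 200 per condition)
keep a full benchmark run under a minute on a single CPU; all sizes
scale up through `SimulationConfig`.

## Numerical choices and edge cases

- Weight rows sum to 1 within 1e-12; empty rows (isolated genes) are
  zero, not NaN.
- A sample with zero expression variance across genes is an error named
  after the sample (the LMI denominator vanishes).
- Logistic separation is detected via the fitter's perfect-separation
  diagnostics and routed to the untestable path.
- The lfdr histogram is degenerate (error) when all mass falls in ≤ 3
  bins, e.g. identical statistics.
- Binary outcomes accept 0/1, "0"/"1", or any two labels (mapped by
  sorted order, logged).  Sample order authority is the expression
  matrix; clinical rows are reordered to match.
- Duplicate gene ids are refused rather than collapsed — probe-to-gene
  summarization is upstream preprocessing with no single right answer.
- Gene identifiers are opaque strings; no symbol mapping is attempted.

## Known limitations

- The empirical-null fallback (theoretical N(0, 1)) is a pragmatic
  choice outside the sparse-signal regime; lfdr values under the
  fallback are rankings more than calibrated posteriors.
- Community detection optimizes modularity greedily; it can merge small
  communities a global optimizer would keep apart (the resolution
  limit inherent to modularity).
- Enrichment treats gene sets as flat lists; ontology-aware conditional
  testing is out of scope.
- Survival association fits one Cox model per gene; on panels of tens
  of thousands of genes this is the slowest path (seconds per thousand
  genes).
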
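# dnlc — differential network local consistency analysis

Biological networks are static summaries of a dynamic system: the
functional relations between genes switch on and off with disease
status, treatment response or developmental stage.  Classical
differential expression asks whether a gene's *level* changes with a
clinical outcome; `dnlc` asks whether the *co-expression consistency of
a gene's network neighborhood* changes — a complementary signal that
standard t-test pipelines are blind to.

The package is aimed at computational biologists who have a gene
expression matrix, an interaction network over the same genes, and a
clinical outcome (continuous, binary, or survival), and want to find
genes and network modules whose local expression consistency tracks the
outcome.

## The statistic

The network is treated as a map and each gene's local consistency in
each sample is scored by **Local Moran's I** from spatial statistics.
With normal-score-transformed expression z, the score for gene *i* in
sample *k* is

    I_ik = (z_ik − z̄_k) / σ_k² · Σ_{j≠i} w_ij (z_jk − z̄_k)

where z̄_k and σ_k² are the mean and (population) variance of expression
across genes in sample *k*, and w_ij are truncated-Gaussian weights of
the hop distance d_ij,

    w_ij ∝ exp(−d_ij²/2) for d_ij ≤ 2,   w_ij = 0 otherwise,

row-normalized so Σ_{j≠i} w_ij = 1.  A large positive I_ik means gene
*i* and its neighborhood are consistently high or low together in that
sample; a large negative value marks a spatial outlier.

Per gene, the LMI profile across samples is linked to the outcome by a
generalized linear model

    E(y | LMI, confounders) = g⁻¹(α·LMI + Σ_m β_m·confounder_m)

(linear, logistic, or Cox proportional hazards with Efron ties,
according to the outcome type).  The per-gene Wald statistics are pooled
into a two-component mixture f(t) = π₀ f₀(t) + (1−π₀) f₁(t) with an
empirically fitted Normal null f₀, and genes with local false discovery
rate lfdr(t) = π₀ f₀(t)/f(t) ≤ 0.2 are reported as **differential
consistency (DC) genes**.  DC genes and their direct neighbors are then
grouped into network communities by fast-greedy modularity maximization,
with optional hypergeometric gene-set over-representation per community.

## Worked example

The built-in generator simulates the exact situation the method is for:
expression with network-decaying correlation `Σ_ij = c^{d_ij}`, where
the correlation constant is switched from `c = 0.2` to `b = 0.8` inside
the 2-hop neighborhoods of five randomly chosen centers for half the
samples — a change in local consistency with **no change in mean
expression**.

```python
from dnlc import SimulationConfig, run_benchmark, simulate_dataset, run_dnlc

config = SimulationConfig(m=500, n=200, base_corr=0.2, changed_corr=0.8,
                          seed=7, n_reps=3)
result = run_benchmark(config)
print(result.summary().to_string(index=False))

dataset = simulate_dataset(config, seed=7)
res = run_dnlc(dataset.expression, dataset.network, dataset.clinical())
dc = res.association[res.association["is_dc"]]
recovered = dataset.truth[dc["gene_id"]].mean()
print(f"{len(dc)} DC genes at lfdr <= 0.2; "
      f"{100 * recovered:.1f}% of them are truly perturbed nodes")
```

prints

```
method  mean_pr_auc  sd_pr_auc
    de     0.365808   0.041185
  dnlc     0.942696   0.043331
175 DC genes at lfdr <= 0.2; 98.9% of them are truly perturbed nodes
```

The DNLC pipeline ranks the truly perturbed nodes near-perfectly
(PR-AUC ≈ 0.94), while the differential-expression baseline stays at the
prevalence floor (≈ 0.37 here, because roughly that fraction of nodes is
perturbed) — the consistency change carries no mean signal for a t-test
to find.

The same analyses are available from a shell:

```sh
dnlc simulate  --m 500 --n 200 --c 0.2 --b 0.8 --reps 3 --seed 7 --out sim/
dnlc run       --expr sim/rep0/expression.tsv --network sim/rep0/network.edgelist \
               --clinical sim/rep0/outcome.tsv --outcome-col outcome \
               --outcome-type binary --out results/
dnlc communities --association results/association.tsv \
               --network sim/rep0/network.edgelist --out modules/
dnlc benchmark --m 500 --n 200 --c 0.2 --b 0.8 --reps 5 --seed 7 --out bench/
```

`dnlc run` also accepts `--outcome-type survival --time-col T --event-col E`
for survival outcomes and `--confounders age,sex` for adjustment.

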
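# admixcompare

Tools for a question conservation and population geneticists keep running
into: **do a handful of highly polymorphic microsatellites and thousands of
biallelic SNPs tell the same story about population structure and genetic
diversity?** The package implements the full comparative workflow — DArT-style
SNP quality filtering, Bayesian admixture-model clustering, choice of the
number of clusters K, label-switching-aware comparison of ancestry matrices
within and across marker types, and spatial gradients of individual
heterozygosity — together with a paired-marker simulator so every stage is
testable against known truth.

## The models at the core

**Admixture model with correlated allele frequencies.** Individual *i* has
ancestry proportions *q<sub>i</sub>* over *K* clusters
(*q<sub>i</sub>* ~ Dirichlet(α)); each allele copy at locus *l* originates
from cluster *k* with probability *q<sub>ik</sub>* and is drawn from that
cluster's frequencies *p<sub>kl</sub>*. Clusters drift around a shared
ancestral pool: *p<sub>kl</sub>* ~ Dirichlet(π<sub>l</sub>(1−F<sub>k</sub>)/F<sub>k</sub>)
with π<sub>l</sub> ~ Dirichlet(λ), so *F<sub>k</sub>* ≈ the cluster's FST
from the pool. A Gibbs sampler (with Metropolis updates for α, F, π and
optionally λ) returns the posterior-mean ancestry matrix Q, allele
frequencies P and the log-likelihood trace.

**Comparisons.** Replicate runs and marker panels are aligned by the column
permutation maximizing the Symmetric Similarity Coefficient
SSC = 1 − ‖Q₁ − Q₂Π‖<sub>F</sub>/√(2N) (an exact assignment problem). K is
chosen with Pr[X|K] = mean(lnL) − var(lnL)/2, Evanno's
ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(K), a parsimony index, and Gelman–Rubin
convergence checks. Per-individual admixture is the Coefficient of Admixture
CA<sub>i</sub> = −Σ<sub>k</sub> q<sub>ik</sub> ln q<sub>ik</sub> / ln K
(0 = single-cluster ancestry, 1 = uniform). Diversity is standardized
multilocus heterozygosity, sMLH (mean 1 under complete data), with Pearson
cross-marker correlation and OLS latitude/longitude gradient models.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from admixcompare import (SimConfig, simulate_dataset, full_filter_chain,
                          McmcOptions, run_admixture_mcmc, align_qmatrices)

cfg = SimConfig(K_true=2, n_individuals=60, n_snp_loci=300,
                alpha_sim=0.05, F_k=(0.05, 0.05), seed=1)
snp, microsat, report, truth = simulate_dataset(cfg)

filtered, audit = full_filter_chain(snp, report)
run = run_admixture_mcmc(filtered, K=2,
                         McmcOptions(burnin=400, iterations=400,
                                     record_interval=5, seed=3))
res = align_qmatrices(truth.true_Q, run.Q)
print(f"SSC vs truth: {res.ssc:.3f}")
```

This prints `SSC vs truth: 0.944`: after resolving label switching, the
posterior-mean ancestries of the 60 simulated individuals are nearly
identical to the generating ancestries (SSC = 1 would be an exact match).

The numbered scripts under `analysis/` run the same workflow end to end and
narrate their findings; on the reference dataset (two populations at
F = 0.05, 300 SNPs vs 12 microsatellites) step 03 prints, for SNPs,

```
snp: delta-K peaks at K=2
 K  mean_lnP  sd_lnP  ...  parsimony_index  gelman_rubin  delta_k
 1 -17031.04    7.47  ...              NaN          1.00      NaN
 2 -16764.40   28.92  ...             0.79          1.02     9.27
 3 -16765.74   23.69  ...             0.53          1.10     3.22
 4 -16843.48  102.10  ...             0.38          1.10      NaN
```

— the true K = 2 wins on ΔK and the parsimony index with well-converged
replicates (GR ≤ 1.05 at K ≤ 2) — while the 12-locus microsatellite panel
yields noisier, multi-modal solutions at every K, and step 05 recovers the
simulated southern-refugium diversity cline (β_lat = −0.080 for SNPs at a
configured slope of −0.08 sMLH units per degree).

A command-line interface mirrors the stages
(`admixcompare simulate | filter | cluster | kselect | compare | diversity |
njtree | all`); `admixcompare all --config cfg.yaml` runs the whole pipeline
from a YAML file and writes a manifest alongside the artifacts.

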
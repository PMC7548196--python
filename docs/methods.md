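# Methods

## Scope

`admixcompare` re-creates, as a tested pipeline on synthetic data, a common
comparative design in amphibian and other non-model population genetics:
genotype the same individuals (or localities) with a dense biallelic SNP
panel and a small multiallelic microsatellite panel, infer population
structure with the Bayesian admixture model independently for each marker,
and ask how repeatable, how admixed and how spatially coherent the two
marker types' answers are. Everything runs end-to-end without external
downloads because the generator produces both panels from one known truth.

## Generative model (simulate)

Per marker panel, locus l has ancestral allele frequencies
pi_l ~ Dirichlet(lambda_sim) over J alleles (J = 2 for SNPs; up to
`microsat_allele_count`, default 8, with integer repeat-count labels for
microsatellites). Population k drifts around the ancestral pool following
the correlated-frequencies (F) model:

    p_kl ~ Dirichlet( pi_l * (1 - F_k) / F_k ),

so F_k is approximately that population's FST from the pool (verified in
tests against a brute-force Weir–Cockerham estimator: F = 0.2 gives
theta ~= 0.2). Individual ancestries are q_i ~ Dirichlet(alpha_sim, ...);
each of the 2L allele copies picks an origin k ~ Categorical(q_i), then an
allele from p_kl. Both panels share the same q_i, which is what licenses
cross-marker comparisons. Missing data are injected per diploid call,
independently, with code -9 (STRUCTURE convention).

**Spatial cline.** The refugial-expansion diversity gradient is emulated by
serial founder events: localities are ordered south to north along a
latitude axis and each locality's allele frequencies are a Dirichlet
resample of its southern neighbour's, with the per-step concentration chosen
so expected heterozygosity shrinks by a factor (1 - |slope|) per degree.
Because mean sMLH is 1 by construction, an OLS fit of sMLH on latitude
recovers roughly `gradient_slope` (tests: -0.08/degree recovered within
±0.03 in >= 9/10 seeds, mean signed bias < 0.01 across slopes in [-0.1, 0]).
This founder chain is a deliberate stand-in — no coalescent, recombination,
mutation-rate realism or allele surfing — and is labelled as such; it only
needs to produce a monotone heterozygosity cline. The generator default is
`gradient_slope = 0` (no cline): structure experiments then follow the plain
F-model the clustering assumes, and diversity experiments switch the cline
on explicitly.

**DArT-style locus report.** Per-locus quality fields (RepAvg, call rate,
mean coverage, allele read proportion, contig id) are fabricated with clean
defaults; a `ContaminationPlan` plants loci violating each filter rule with
known identities so filter selections can be checked exactly. Planted
shared-contig groups carry strictly decreasing RepAvg so the expected
survivor is unambiguous.

## SNP filtering

The chain runs in a fixed order: individual call rate, RepAvg, allele read
balance, excess coverage, locus call rate (recomputed after the individual
filter), one SNP per contig, minor-allele frequency. Boundary behaviour is
explicit because it matters for exactness tests: individuals kept when call
rate > 0.35 (strict); loci kept when RepAvg > 0.95 (strict); balance kept on
the closed window [0.15, 0.85]; loci dropped when coverage > 3.5x the median
of loci still in play at that step (midpoint-interpolated median); dropped
when call rate < 0.8; dropped when MAF < 0.02. "Removing a rare allele" is
implemented as removing the locus: on biallelic data deleting one of two
alleles would leave a monomorphic locus. One-SNP-per-contig ties break by
higher recomputed call rate, then lexicographic locus id, so output is
deterministic. MAF is computed after the within-contig deduplication,
following the order in which the rules are stated.

## Admixture clustering (the sampler)

The model is the admixture model with correlated allele frequencies: a
single shared alpha (uniform prior on (0, 10]) for the Dirichlet ancestry
prior, F_k ~ Uniform(0,1) per cluster, pi_l ~ Dirichlet(lambda). Updates per
sweep: latent origins z (categorical Gibbs), q_i (Dirichlet Gibbs), p_kl
(Dirichlet Gibbs under either frequency model), F_k (random-walk Metropolis
on the logit scale, step 0.1), pi_l (Metropolis–Hastings with a
Dirichlet(100*pi + 0.1) independence-style proposal, floored at 1e-6 to keep
observed alleles supported), alpha (random-walk Metropolis, sd 0.05, about
10 sub-steps per sweep — its sufficient statistic is fixed within a sweep,
so extra steps are nearly free and shorten the walk), and optionally lambda
(random-walk Metropolis, uniform prior on (0, 10]). Missing copies are
skipped, never imputed. Posterior means accumulate every
`record_interval`-th post-burnin sweep; the log-likelihood
ln Pr(X | Q, P) = sum over observed copies of ln sum_k q_ik p_kla is
recorded at the same cadence. At K = 1 the frequency model reduces to the
uncorrelated prior.

**Initialization.** The collapsed "no structure" state is strongly
self-trapping under the F-model: a collapse drives F_k towards 0, whose
then-enormous prior concentration pins every p_kl to pi_l, removing the
frequency fluctuations that could nucleate clusters. Chains therefore start
from an informed soft partition: k-means (10 restarts, best inertia) on the
leading principal components of the centred one-hot allele-dosage matrix
places cluster centres, and a Gaussian kernel on centre distances (scale =
a quarter of the mean within-cluster squared distance) converts them to
per-individual weights from which starting origins are sampled. Soft rather
than hard weights matter: genuinely admixed individuals begin with mixed
labels, so the (fast-adapting) alpha cannot lock them pure before they
equilibrate. The stationary distribution is unaffected; `init="random"`
gives a cold start for diagnostics. Validation: posterior 90% intervals
cover true q_ik for >= 80% of entries on model-drawn data, and two seeds
agree up to a column permutation.

**lambda estimation.** At K = 1 with lambda free, three replicate runs are
averaged. The K = 1 model is conjugate (Dirichlet-multinomial), so the exact
lambda posterior mean is computable by quadrature; the sampler agrees with
this oracle to ~0.005 in tests. Note the estimate is mildly shrunk toward
intermediate values by observed-allele ascertainment (loci monomorphic in
the sample contribute nothing), which is inherent to the model, not a
sampler artefact: a lambda_sim = 1 panel of 1,000 loci and 200 individuals
gives ~0.83 (exact posterior: 0.834).

**Run lengths.** Defaults follow the conventional settings for each marker
(SNPs: 30,000 burnin + 10,000 sweeps recorded every 50; microsatellites:
500,000 + 1,000,000 recorded every 5,000, lambda fixed to 1). The analysis
scripts and tests use hundreds of sweeps instead; with the informed start,
recovery and K-selection behaviour at these data sizes is already stable at
that length, and the scaled conditions are stated with each experiment.

## K selection and convergence

* **Gelman–Rubin** on replicate post-burnin log-likelihood traces (the one
  per-step scalar every run logs): W = mean within-chain variance, B/n =
  variance of chain means, Vhat = (n-1)/n W + B/n + B/(mn), statistic
  sqrt(Vhat/W); < 1.05 is read as converged.
* **Pr[X|K]** per run: mean(lnL) - var(lnL)/2 with the plug-in (ddof = 0)
  variance.
* **Evanno delta-K**: |L(k+1) - 2L(k) + L(k-1)| / sd(k), with sd the
  replicate standard deviation of per-run Pr[X|K]; undefined at range ends;
  zero sd yields +inf with a warning.
* **Parsimony index**: the product of run-consistency (mean pairwise aligned
  SSC among the K's replicates) and parsimony (1 - mean CA of the aligned
  consensus). This is an operationalization of "most consistent clusters
  with minimal average admixture"; the published formula lives in software
  we do not re-implement, so the index is isolated behind one function for
  substitution. It is undefined at K = 1 (CA is undefined there).
* **Model-free cross-check**: allele-sharing distance (1 - mean multiset
  overlap/2 over co-typed loci) and Saitou–Nei neighbour joining (via
  scikit-bio, negative branches clamped to zero); on an additive matrix the
  tree reproduces the input distances exactly.

## Q-matrix comparison

SSC(Q1, Q2; P) = 1 - ||Q1 - Q2 P||_F / sqrt(2N). Maximizing over column
permutations decomposes into independent per-column squared-distance costs,
i.e. a linear assignment problem, solved exactly with the Hungarian
algorithm (no greedy fallback is needed at any K); exhaustive enumeration is
kept as an independent oracle in tests. Different K are compared after
zero-padding the smaller matrix, so clusters absent at the lower K map onto
the padding. Modes among replicates are single-linkage groups at aligned
SSC >= 0.9 (a conventional default); each mode's consensus is the mean of
members aligned to its first member; the major mode is the largest, ties
broken by higher mean intra-mode SSC. Locality averaging is the arithmetic
mean of member rows.

The **Coefficient of Admixture** is normalized Shannon entropy,
CA_i = -sum_k q_ik ln q_ik / ln K, which meets both defining endpoints
(0 for single-cluster ancestry, 1 for uniform ancestry). An alternative
satisfying the same endpoints, 1 - K/(K-1)(max_k q_ik - 1/K), is available
behind `method="maxdev"` as a sensitivity check, since the defining
publication leaves the exact formula in supplementary material.

## Diversity

sMLH_i = (fraction of i's typed loci heterozygous) / (mean dataset
heterozygosity h_l of those same loci); loci with h_l = 0 are excluded
(they would deflate denominators without information). With complete data
mean sMLH = 1 exactly — an algebraic identity the tests assert to 1e-9.
Cross-marker agreement is the Pearson correlation over shared individuals;
spatial structure is OLS of individual-level sMLH on latitude and longitude
(individuals, not locality medians, enter the regression; a flag-free helper
for medians exists for mapping). Even-count medians are midpoints.

## Study conditions used in the checks

* Filter exactness: 120 common-variant loci, one planted violation set per
  rule.
* Ancestry recovery: K_true = 2, n = 60, 300 SNPs, F = (0.05, 0.05),
  alpha = 0.05; chains 400 + 400, recorded every 5; MAE after alignment
  < 0.05.
* delta-K detection: K_true = 3, n = 90, 600 SNPs, F = 0.05, alpha = 0.05;
  5 replicates x K in 1..5, chains 250 + 300 recorded every 2 (the Pr[X|K] variance penalty needs
  a dense trace: with ~50 recorded points its sampling noise alone inflates
  the replicate sd that Evanno divides by); peak at
  K = 3 required in >= 8/10 fresh datasets. The panel size matters here:
  with equal drift in all three populations the hierarchy among clusters is
  weak, and at a few hundred loci delta-K reverts to its well-known K = 2
  bias on a sizeable minority of datasets; 600 loci is still 25-50x below a
  real reduced-representation panel but enough for the K = 3 elbow to
  dominate the replicate noise.
* Marker contrast: K_true = 3, n = 40, 2,000 SNPs vs 15 eight-allele
  microsatellites, alpha = 0.1, F = 0.1, 3 replicates per marker, chains
  120 + 120; SNPs must show a higher minimum intra-marker SSC and lower
  mean CA in >= 8/10 repetitions.
* Cline recovery: slope -0.08/degree, n = 90, 500 SNPs, 9 localities.

## What passing tests do and do not show

The generator draws data exactly from the model the sampler assumes (aside
from the founder cline, which deliberately violates it), so these checks
establish internal correctness and calibration — not robustness to
real-data features such as linkage, null alleles, genotyping error
correlated with coverage, uneven sampling, or isolation by distance. The
microsatellite mutation process is a label resample, not stepwise mutation;
only the diversity gradient, never the mutation model, is consumed
downstream. Real-data quantities (e.g. per-species lambda estimates or
gradient p-values) depend on the deposited empirical datasets and are out of
scope here.

## Known limitations

* The sampler is single-chain-per-run and has no tempering; at K well above
  the true K, replicate runs legitimately scatter across modes (the tests
  use this fact rather than fight it).
* Label alignment across K uses zero-padding, not divisive cluster matching.
* The parsimony index is an operationalization (see above).
* NJ trees carry no bootstrap support.
* LOCPRIOR-style sampling-location priors and linkage models are not
  implemented ("no prior information on sample origin" is the setting
  throughout).
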
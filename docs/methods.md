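# Methods

`sealdrift` implements the population-genomic toolkit for studying a marine
mammal population that crashed under exploitation and then recovered:
likelihood-free (ABC) choice among piecewise demographic scenarios from a
single SNP panel, and a forward drift null for detecting loci whose allele
frequencies changed too fast across sequenced cohorts. This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic-data tests do and do not establish.

## Demographic scenarios and coalescent simulation

Four step-function histories of diploid effective size are compared, in
scaled units with the present size fixed at N0 = 100,000 and the post-glacial
expansion fixed at te = 10,000 generations before present:

1. constant N0;
2. expansion only — size Npe before te;
3. bottleneck only — N0 until tr, Nb between tr and tb, Npb earlier;
4. expansion and bottleneck — all of the above, Npe before te.

Free parameters have independent uniform priors: Npe ∈ (1,000, 10,000),
Nb ∈ (100, 10,000), Npb ∈ (20,000, 100,000), tr ∈ (1, 100), tb ∈ (100, 5,000),
with tr < tb enforced by rejection. Sizes change instantaneously at event
times; scaled times are treated as generations. No generation-time or
census-size calibration is attempted — only relative size changes at relative
times are inferred, so the same machinery serves both study species.

Each locus is an independent Kingman coalescent genealogy of 2n gene copies.
The simulator samples inter-coalescent waiting times in rescaled time (the
integrated coalescent rate, piecewise linear for a step-function history) and
maps them back through the inverse rate integral; no per-generation iteration
and no explicit tree topology is needed. A SNP is created by placing exactly
one mutation uniformly on the total branch length, using two exact properties
of the neutral coalescent: the mutation falls in the period with k ancestral
lineages with probability proportional to k·T_k, and the number of sampled
copies below a random branch among k is distributed as
P(i | k) = C(n−i−1, k−2)/C(n−1, k−1). Every simulated locus is therefore
polymorphic in the sample — the standard SNP-panel convention. Mutation rate
never enters. The sampler is validated against closed-form pairwise
expectations, a naive per-generation pairwise simulator, and msprime tree
heights and lengths under a three-epoch history.

A consequence of the single-mutation convention worth stating explicitly:
per-locus gene diversity depends only on *relative* branch lengths, so a
bottleneck in which all lineages coalesce is exactly equivalent to the
constant-size null (Kingman tree shape is size-invariant), while a partially
coalescing bottleneck *raises* mean conditional diversity by creating long
deep branches. Unconditional heterozygosity would fall after a bottleneck;
the conditional statistic moves the other way. The test suite asserts the
computed direction.

## Summary statistics and ABC

Each dataset is summarized by four statistics of the per-locus gene-diversity
distribution h_i = (n/(n−1))·2p̂(1−p̂): the proportion of zero values, the
mean and variance (n−1 denominator) of the nonzero values, and the mean of
the complete distribution. For fully typed single-population simulated data
the proportion of zeros is identically 0; it is retained for observed panels
(which may contain cohort-monomorphic loci) and automatically dropped from
distances whenever its reference-table standard deviation is zero.

Model choice: datasets are simulated from the priors into a reference table
(default 25,000 per scenario at full scale; 5,000 per scenario in the tests
and the acceptance script — the desk-scale sizes used for every number this
package reports). Distances are Euclidean on summaries standardized by the
reference-table standard deviations. The closest 1% of rows gives (a) the
rejection posterior — scenario frequencies with binomial normal CIs — and
(b) a weighted multinomial logistic regression of scenario on the
standardized summary differences, with Epanechnikov weights on distance and
a small ridge penalty (1e-3) so separable classes remain well-posed,
evaluated at the observation; its 95% CIs come from the delta method on the
inverse penalized Hessian. An observation outside the simulated range of any
summary raises a model-fit warning flag.

Parameter posteriors use the standard logit-transform regression adjustment:
accepted draws are mapped by logit((θ−lo)/(hi−lo)) (values at a bound nudged
1e-6 into the interior, with a count logged), shifted by a weighted
local-linear regression on the standardized summary differences,
back-transformed, and summarized by weighted mean, median and 2.5/97.5%
quantiles — all inside the prior support by construction.

Confusion validation simulates pods (pseudo-observed datasets) with
prior-drawn parameters under each scenario, classifies each by arg-max
logistic posterior, and reports, per scenario, the fraction of pods from the
*other* scenarios (pooled equally) that selected it. At desk scale
(5,000 sims/scenario, 200 pods per alternate scenario, 1,000 loci, 32
diploids, no MAF) the wrong-selection rate for scenario 4 computed by
`scripts/acceptance.py` is about 5%.

Identifiability caveat: with three effective summaries, the bottleneck size
Nb is well recovered only when the bottleneck is severe — duration
(tb−tr)/(2Nb) of order 1, so that most lineages coalesce inside it. The
parameter-recovery test uses severity ≈ 1.2 (tb = 2,500, tr = 50,
Nb = 1,000); at severity ≈ 0.2 the posterior collapses toward the prior and
medians sit near mid-prior regardless of estimator details.

## Wright–Fisher drift under logistic growth

The temporal null is a single unstructured population whose census size
follows N_{t+1} = N_t + rN_t(1 − N_t/K), one step per calendar year, with a
binomial Wright–Fisher drift step (2N_e gene copies; N_e = ne_ratio × census,
ne_ratio default 1) applied each year *before* the census update. Census
sizes are rounded to the nearest integer (ties to even) and floored at 2.
Mutation is not modeled; over a few decades its contribution is negligible.
Treating one calendar year as one generation is deliberate — the growth rates
in the presets are annual survey rates applied per model step — and means the
null slightly overstates drift per year relative to the ~10-year generation
time of seals; the envelope is therefore conservative for outlier calling.

Two presets encode the literature parameterizations: gray seals at Sable
Island 1970–2015 (start 5,000; r = 0.13 for 25 years then 0.04 for 20;
K = 500,000) and Northeast-US harbor seals 1995–2015 (start 67,500;
r = 0.066; K = 100,000). Trajectories are seeded from observed frequencies
of the oldest sequenced cohort and sampled at the cohort years (rounded to
whole years since start). Cohort sampling noise can be included
(binomial 2n_c draws, the default, so simulated series carry the same
sampling error as the observed cohort frequencies) or excluded
(population-frequency mode); both are exposed because the choice is not
dictated by the model.

## Temporal outlier scan

Every observed and simulated locus gets an OLS regression of cohort allele
frequency on calendar year (unweighted by default; gene-copy weighting is a
flag). The slope p-value is the two-sided t test with n−2 df; zero residual
variance (perfect fit or constant series) is flagged degenerate and excluded
from envelopes and distribution tests, with a logged count. The envelope is
the maximum |slope| over all simulated loci — no p-gating of simulated loci;
an observed locus is an outlier iff its own p < 0.05 *and* |slope| exceeds
the envelope. (A variant restricting the envelope to individually
significant simulated loci exists behind a flag for sensitivity analysis.)
The scan also reports a two-sided variance-ratio F between observed and
simulated slopes and a pooled two-sample t of the means.

Under the null (observed series generated by the same simulator), exceeding
the maximum of 1,000 simulated slopes has per-locus probability ≈ 1/1001, so
a 1,000-locus scan should flag only a handful of loci; the calibration test
confirms a median ≤ 5 over 20 replicate scans. Power is checked by planting
loci under deterministic positive selection (p′ = p(1+s)/(1+ps) applied
before drift each year): s = 0.15/yr from p0 = 0.2 over a 45-year, 5-cohort
design with 30 diploids per cohort is detected in well over 80% of cases.

## Diversity metrics

Allelic richness is hypergeometric rarefaction,
A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)], exact against exhaustive enumeration of
all subsamples for N ≤ 12. The rarefaction size g is configurable because a
real design may standardize to the smallest cohort or the smallest colony;
g = "auto" uses the minimum typed gene-copy count over loci and groups so
every locus is rarefiable under the 80%-presence filter. Gene diversity
defaults to the plain 2p(1−p) with an n/(n−1) unbiased option — both are
exposed because either convention appears in the field's software. Cohort
and colony comparisons treat loci as replicates: one-way fixed-effects
ANOVA, pooled-variance two-sample t, and a two-sided variance-ratio F;
zero-variance degeneracies return a flag, not a fabricated 0 or 1.

## Panel filters

`filter_group_presence` implements both presence rules — typed in ≥ X% of
individuals in at least one group ("any"; X = 0.8 gives the r80 panel) or in
every group ("all", the within-colony rule used before diversity and trend
analyses); the single-cohort ABC input uses the 90% rule. The MAF filter
uses the pooled folded frequency over all non-missing calls, with an
inclusive threshold. One SNP per RAD locus is kept by lowest coordinate
("first") or fewest missing calls ("most_complete", ties to first); both
rules exist because tie-breaking is not standardized.

## Synthetic data

The generator emulates the study design: one population evolving under the
drift-plus-logistic-growth null, multiple colonies as sampling partitions,
2–5 cohorts spanning decades, 11–34 diploids per cohort, thousands of
biallelic loci, founding frequencies from a low-frequency-enriched spectrum
(mass ∝ 1/i on a gene-count grid, by default), Hardy–Weinberg genotype
pairing, i.i.d. per-genotype missingness, and optional planted selected
loci with exact deterministic effect sizes. What it does *not* emulate:
linkage, RAD-locus dropout via restriction-site polymorphism, per-library
coverage structure, genotyping error, or real population structure between
colonies. Passing tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to those real-data
complications.

## Problem sizes used in the shipped tests and acceptance script

Reference tables: 5,000 simulations per scenario (the study's tool used
250,000); pods: 200 per alternate scenario for confusion rates, 50 for
bottleneck-support, 20 for parameter recovery; outlier scans: 1,000 loci,
20 null replicates, 2 planted-power replicates of 25 planted loci each.
These sizes keep every reported quantity's Monte-Carlo error well inside the
tolerances asserted, and are the package's chosen desk-scale defaults.

## Known limitations

- Single-population models only: no migration, no structure, no two-sex or
  age-structured demography.
- The ABC stage does not model per-locus missingness; observed panels are
  presence-filtered upstream instead.
- Exact numeric agreement with DIYABC is not claimed: that tool's distance
  normalization and logistic weighting are not published in sufficient
  detail; the choices here (SD standardization, Epanechnikov weights, ridge
  1e-3) are documented and fixed by configuration.
- The annual-generation convention makes the drift null conservative for
  long-generation species, as noted above.
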
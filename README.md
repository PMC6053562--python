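# sealdrift

Demographic inference for temporally sampled SNP panels from bottlenecked,
recovering populations — built around the Northwest Atlantic seal study
design: biological collections spanning half a century of population
recovery, genotyped at thousands of RAD SNPs.

The package answers two questions a population of this kind poses:

1. **Looking back** — does the contemporary genome still carry the signature
   of the historical crash? `DemographicABC` performs approximate Bayesian
   computation over four piecewise effective-size histories (constant;
   post-glacial expansion; exploitation bottleneck; expansion *and*
   bottleneck), simulating single-mutation coalescent SNP panels from
   uniform priors, summarizing each panel by four statistics of the
   per-locus gene-diversity distribution, and estimating posterior model
   probabilities by rejection and by weighted multinomial logistic
   regression on the closest 1% of simulations. Parameter posteriors use
   the logit-transform local-linear regression adjustment; validation
   reports wrong-selection (confusion) rates on pseudo-observed datasets.
2. **Looking forward** — did any locus change frequency faster than drift
   allows during recovery? `TemporalOutlierScan` simulates a neutral
   Wright–Fisher null in a population growing logistically,
   N_{t+1} = N_t + rN_t(1 − N_t/K), one binomial drift step per year,
   seeded from the oldest cohort's frequencies; it regresses every observed
   and simulated locus on calendar year and flags loci that are both
   individually significant (p < .05) and steeper than the *maximum*
   simulated slope.

Supporting modules provide the shared currency (`GenotypeMatrix` from
VCF + metadata, with r80/90% presence filters, pooled-MAF filtering and
one-SNP-per-RAD-locus thinning), rarefied allelic richness
A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)] and gene diversity 2p(1−p) with cohort
comparison tests, a synthetic-data generator with known ground truth
(planted selection, missingness, Hardy–Weinberg sampling), and a YAML-driven
CLI (`sealdrift synth|diversity|simulate-wf|scan-outliers|abc-fit|abc-validate|full-study`).

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

## Worked example

Simulate a Sable-Island-shaped study — five cohorts, 1973–2015, 28–32
diploids each, 2,000 loci drifting through the gray-seal logistic recovery
(5,000 → K = 500,000; r = 0.13 then 0.04), 20 loci planted under selection
s = 0.15/yr from p₀ = 0.2, 5% missing genotypes — then scan it and run the
ABC stage on its newest cohort:

```python
import numpy as np
from sealdrift import (DemographicABC, TemporalOutlierScan, GRAY_SEAL_SABLE,
                       generate_cohort_study)

gm, truth = generate_cohort_study(n_loci=2000, n_planted=20, s=0.15,
                                  planted_p0=0.2, missing_rate=0.05, seed=42)

scan = TemporalOutlierScan.from_genotypes(gm, GRAY_SEAL_SABLE)
result = scan.fit(seed=1)
print(result.summary())
```

```
Temporal allele-frequency outlier scan
============================================================
observed loci: 1990 (+0 dropped incomplete)   simulated loci: 1990
slope envelope (max |simulated slope|): 0.006362 / yr
outliers (p < 0.05 and |slope| > envelope): 20
variance F = 2.392  df = (1960, 1619)  p = 0
mean-slope t = 2.447  p = 0.0145
```

All 20 outliers are exactly the planted loci
(`set(result.outlier_ids) == set(truth.planted)`): no neutral locus out-ran
the drift envelope, every selected one did. The variance-F line says the
observed slope distribution is over-dispersed relative to drift — the same
diagnostic that flags selection-like change in real panels — while the mean
slope barely differs.

```python
model = DemographicABC.from_genotypes(gm, n_loci=1000)
res = model.fit(sims_per_scenario=5000, seed=2)
print(res.summary())
```

```
ABC demographic model choice
============================================================
loci: 1000   diploids: 31   MAF filter: none
reference rows: 20000   accepted: 200 (top 1%)
degenerate summaries dropped from distance: prop_zero

scenario   logistic %             95% CI  rejection %
       1        92.66     (  0.0, 100.0)        95.50
       2         0.00     (  0.0,   0.0)         0.00
       3         0.16     (  0.0,   4.9)         0.50
       4         7.19     (  0.0, 100.0)         4.00
...
```

The verdict is correct: this synthetic panel's founding spectrum carries no
deep bottleneck signature, and the constant-size scenario 1 wins with ~93%
posterior probability. Run the same two steps on a panel simulated under
scenario 4 (`generate_abc_study`) and the bottleneck scenarios take the
posterior instead.

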
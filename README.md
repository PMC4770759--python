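# mrnasig

Discovery and validation of a prognostic mRNA-expression signature for
cytogenetically normal acute myeloid leukemia (CN-AML), packaged as a
reusable, tested pipeline.

CN-AML patients — roughly half of all AML — lack the karyotype
abnormalities that usually drive risk stratification, so expression-based
scores are a natural refinement. The pipeline implemented here builds such
a score from a probe-level expression matrix and a clinical table:

1. **Response-associated differential expression.** Per-probe
   equal-variance Student *t*-test between patients refractory to
   induction chemotherapy (PR) and patients in continuous complete
   remission (GR); keep probes with *P* < 0.05 and |Δlog₂| > log₂(2).
2. **Survival filter.** For each surviving probe, a univariate Cox
   proportional-hazards fit of overall survival (OS) on the probe's
   z-transformed expression among intensively treated patients
   (transplanted patients censored at stem-cell infusion); keep Wald
   *P* < 0.01. The result is the signature.
3. **Risk score.** For patient *j*, `score_j = Σ_g z_gj` over signature
   probes *g*, where `z_gj = (x_gj − mean_g) / sd_g` — equal unit weights,
   no refitting. The cohort is dichotomized at the median score for
   Kaplan–Meier / log-rank comparison; the continuous score enters Cox
   models (HR per score unit).
4. **Permutation validation.** The whole scoring *system* is compared with
   10,000 systems built from random same-size probe sets: the empirical
   *P* is the fraction of random systems achieving a smaller Cox Wald *P*
   than the proposed score.
5. **Downstream characterization.** Score-group associations with
   mutations and clinical covariates (uncorrected Pearson χ², Fisher,
   Mann–Whitney), differential expression between the mean ± 1 SD score
   tails, and GSEA-style running-sum enrichment with gene-permutation
   significance.

External cohorts are scored by collapsing probes to genes (largest
coefficient of variation per gene), z-transforming within the cohort, and
matching the signature by gene symbol.

Because the discovery cohorts behind published signatures are not
redistributable, the package ships a synthetic-cohort generator
(`mrnasig.cohort`) with a planted signature: a latent risk factor `r ~
N(0,1)` drives a co-expressed probe block (`x = a + b·r + ε`), exponential
survival times (`h(t) = h₀·e^{β r}`), induction response, and mutation
flags. Ground truth is returned alongside, so recovery and calibration are
testable end to end.

## Worked example

```python
from mrnasig import SignatureModel, CohortConfig

model, truth = SignatureModel.from_synthetic(CohortConfig(seed=3))
results = model.fit()
print(results.summary())
```

```
Prognostic signature discovery
==================================
Samples: 160 (treated 105, PR 22, GR 83)
Stage 1 (t-test P < 0.05, fold > 2.0): 15 probes selected
Stage 2 (univariate Cox P < 0.01): 5 probes in signature

           gene    cox_p   hr  ci_low  ci_high
probe_id
SIGP0002  SIG02  0.00225 1.52    1.16     1.99
SIGP0004  SIG04 0.000442 1.65    1.25     2.19
SIGP0006  SIG06 0.000185 1.69    1.28     2.22
SIGP0007  SIG07  0.00063 1.72    1.26     2.34
SIGP0009  SIG09  0.00166 1.58    1.19     2.11

Median-split log-rank: chi2 = 14.664, P = 0.000128
Median OS (high: 12.6 mo, low: 42.9 mo)
Cox on continuous score: HR 1.186 per unit (95% CI 1.101-1.278), P = 6.59e-06
```

Reading the output: 15 probes separated responders from refractory
patients at ≥ 2-fold; 5 of them (all planted `SIGP*` probes) also carried
a per-probe hazard ratio of 1.5–1.7 per z-unit with Cox *P* < 0.01. The
equal-weight score built from them splits the treated cohort into a
high-score arm with median OS 12.6 months versus an arm whose median is
42.9 months, and each score unit multiplies the hazard by 1.19. A
permutation test (`results.permutation_test(n_iter=10_000, seed=0)`)
reports how often random 5-probe systems beat this — for planted cohorts
the empirical *P* is typically reported as a bound, e.g. `< 1.00e-04`.

The same objects drive transfer: `results.score_external(expr, clinical)`
collapses, standardizes, maps by gene symbol and reports log-rank and
per-unit Cox statistics for a validation cohort.

A thin CLI mirrors this flow (`mrnasig simulate | discover | validate |
associate`); `mrnasig associate --counts 47 32 31 48` checks a published
2×2 association from its printed counts.

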
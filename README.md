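# megwas

Association and heterogeneity testing for **multi-ethnic case-control
GWAS**, plus a fully seeded simulation engine for studying type I error and
power under population structure.

GWAS cohorts increasingly mix individuals of African, East Asian, South
Asian, Hispanic and European ancestry, often with admixture, so samples
cannot be cleanly split into homogeneous strata. `megwas` implements the
pooled-analysis alternative:

* **Association.** For variant *j* with additively coded dosages *g* and
  axes of genetic variation (AGV) **x** — the leading eigenvectors of a
  genetic relatedness matrix (GRM) —

  logit P(y = 1) = α + β·g + **γ**′**x**,

  tested by a 1-df likelihood-ratio test of β = 0. The AGV absorb
  confounding between phenotype and ancestry, within and between ethnic
  groups.

* **Heterogeneity between ancestry groups.** The model is extended with
  interactions between the variant and the first two AGV (the axes that
  separate the major ancestry groups):

  logit P(y = 1) = α + β·g + **γ**′**x** + λ₁·g·x₁ + λ₂·g·x₂,

  and a 2-df likelihood-ratio test of λ₁ = λ₂ = 0 detects allelic effects
  that differ along the ancestry axes — e.g. a weaker odds ratio in East
  Asian ancestry individuals.

* **The meta-analysis comparator.** Per-population association with
  population-specific AGV, pooled by fixed-effects inverse-variance
  weighting, with Cochran's Q for between-population heterogeneity.

* **Supporting machinery.** VCF/dosage-table I/O, GWAS quality control
  (call rates, exact Hardy–Weinberg test, MAF/info filters, palindromic
  variants, pi-hat relatedness pruning), LD pruning, GRM/PCA, AGV
  screening, genomic control λ and λ₁₀₀₀, and conditional and generic
  covariate-interaction tests.

* **Simulation engine** (`megwas.simstudy`). A 10-population cohort
  (2000 individuals per population, 20 000 total) with Balding–Nichols
  allele frequencies, Beta-distributed individual admixture for the five
  admixed populations, case:control ratios that confound phenotype with
  ancestry ("moderate"/"extreme" structure), and retrospective causal-SNP
  sampling under five models of between-ancestry effect heterogeneity.
  Everything is reproducible from one master seed.

## Worked example

Simulate one scenario from the command line — a variant with opposing
log-odds ratios of ±0.4 in African vs all other ancestry groups, moderate
structure, 200 replicates:

```bash
megwas simulate --model african_vs_others --structure moderate \
    --effect-size 0.4 --replicates 200 --seed 7 --out power.tsv
```

which prints (abridged to the genome-wide threshold rows):

```
       analysis             model structure  effect_size    threshold  power    mc_se  n_replicates
        glm_agv african_vs_others  moderate          0.4 5.000000e-08  0.290 0.032086           200
 glm_unadjusted african_vs_others  moderate          0.4 5.000000e-08  0.630 0.034139           200
     meta_fixed african_vs_others  moderate          0.4 5.000000e-08  0.275 0.031573           200
het_interaction african_vs_others  moderate          0.4 5.000000e-08  0.955 0.014659           200
  het_cochran_q african_vs_others  moderate          0.4 5.000000e-08  0.940 0.016793           200
```

Reading the rows: the AGV-adjusted pooled test (`glm_agv`, power 0.290)
and the fixed-effects meta-analysis (`meta_fixed`, 0.275) are
indistinguishable within Monte-Carlo error, as they are in every scenario.
The *unadjusted* pooled test appears more powerful (0.630) — but that is
confounding, not signal: the case:control gradient mimics the effect
direction, and the same test rejects wildly under the null (its type I
error is the thing the AGV adjustment fixes). The effect flip of ±0.4
between ancestry blocks is detected by both heterogeneity tests, the 2-df
SNP×AGV interaction (0.955) ahead of Cochran's Q (0.940), reflecting its
fewer degrees of freedom. `mc_se` is the binomial Monte-Carlo standard
error of each power estimate over the 200 replicates.

The same study from Python:

```python
import megwas as mw

scenario = mw.make_scenario("african_vs_others", "moderate", 0.4)
table = mw.run_replicates(scenario, seed=7, n_replicates=200)
print(table.table)
```

For real data the entry points are `megwas qc`, `megwas pca`,
`megwas assoc` (flags `--het`, `--condition-on`, `--covariates`) and
`megwas meta`, reading VCF (GT or DS fields) or tab-delimited dosage
tables plus a sample-ID-keyed phenotype table, and writing tab-delimited
summary statistics (risk/other allele, RAF, OR with 95% CI, P, P_het,
info).

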
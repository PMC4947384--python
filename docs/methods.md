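# Methods

## Statistical model

`megwas` analyses a dichotomous phenotype **y** and genotype dosages **G**
for a cohort of unrelated, ancestrally diverse individuals in a logistic
modelling framework. Population structure is represented by axes of
genetic variation (AGV): eigenvectors of a genetic relatedness matrix
(GRM), estimated here as principal components of the column-standardized
dosage matrix. For variant *j*:

* association: `logit P(y=1) = α + β g_j + γ'x`, 1-df LRT of β = 0, with
  **x** the retained AGV plus any extra covariates (sex, age, ...);
* heterogeneity: the design adds `g_j·x₁` and `g_j·x₂` (interactions with
  the two leading ancestry axes, main effects always retained so the
  models nest), 2-df LRT of λ₁ = λ₂ = 0;
* conditional analysis appends another variant's dosages to the
  covariates; a generic 1-df covariate×SNP interaction test (e.g. age×SNP)
  is also provided;
* the comparator arm tests each population separately with
  population-specific AGV and pools (β, SE) by fixed-effects
  inverse-variance weighting; Cochran's Q (χ², k−1 df) measures
  between-population heterogeneity.

Assumptions: unrelated samples (relatedness is removed in QC by greedy
pi-hat>0.2 pruning), additive allelic coding on the log-odds scale, and
structure adequately captured by the leading AGV. The link is fixed to
logit; quantitative-trait links are out of scope.

## Numerical choices

Logistic likelihoods are maximised by Newton/IRLS with step-halving;
convergence at score sup-norm < 1e-8 or relative log-likelihood change
< 1e-10, capped at 100 iterations. LRT statistics are clipped at zero
(slack 1e-6 triggers an error instead, since the null is nested by
construction). Rank-deficient designs raise a collinearity error naming
the offending columns (QR with pivoting).

Separation deserves care in structured case-control data. Complete
separation — the fit classifies every observation perfectly, so no
maximiser exists — is flagged and no P value is reported.
*Quasi*-separation of nuisance covariates is, by contrast, expected here:
under extreme structure an all-control ancestry group is pushed towards
fitted probability 0 along an ancestry axis, the coefficient diverges but
the log-likelihood converges to its supremum. Likelihood-ratio tests
remain well defined in that limit, so the fit simply stops on the
log-likelihood plateau. (A coefficient-magnitude cutoff is the wrong
criterion: AGV columns are unit-norm, so entries are O(n^-1/2) and
legitimate coefficients are numerically huge.)

PCA of cohort-scale panels never materialises the n×n GRM: AGV come from
an SVD of the standardized dosage matrix (identical eigenvectors), using
randomized subspace iteration (fixed sketching seed, 8 power iterations)
when the panel is large. Eigenvector signs are pinned (largest-magnitude
loading positive) so the interaction coefficients λ₁, λ₂ are reproducible.
Missing dosages are mean-imputed inside GRM/PCA only; association tests
drop samples missing the tested variant.

The Hardy–Weinberg test is the plain (not mid-p) two-sided exact test,
summing probabilities of all heterozygote configurations no more likely
than the observed one. IBD (pi-hat) uses the method-of-moments IBS
decomposition with allele frequencies from the analysed sample, after
hard-calling dosages at 0.5/1.5; both conventions are stated here because
only "exact P" and "IBD metrics" are standard vocabulary, not formulas.
LD pruning scans left-to-right with a 50-variant trailing window and drops
a variant when r² ≥ 0.01 with any retained neighbour.

## Simulation design

The generator emulates a multi-ethnic cohort built from the ten Phase-3
HapMap reference populations — MKK, ASW, LWK, YRI (African), CHB/JPT, CHD
(East Asian), GIH (South Asian), MXL (Hispanic), CEU, TSI (European) —
with 2000 individuals each (20 000 total). Haplotype resampling is
replaced by a Balding–Nichols hierarchy: per SNP, an ancestral frequency
p₀ ~ U(0.1, 0.9), continental-block frequencies Beta-distributed around p₀
with differentiation F (African 0.15, other blocks 0.10), population
frequencies around their block with F_within = 0.02, all clipped to
[0.01, 0.99]. The five admixed populations (ASW, MKK, LWK, MXL, GIH) mix
their own frequency with the European block frequency through
individual-level admixture proportions a_i ~ Beta(8, 2), drawn once per
individual. These F values are realistic continental-scale differentiation
levels; they are configuration, not constants.

Background panel: 24 000 independent SNPs (independence stands in for LD
pruning) from which the 10 multi-ethnic AGV and the 4 population-specific
AGV per population are estimated. The panel size is chosen so that AGV
estimation noise is negligible at the Monte-Carlo resolution of the
replicate studies: residual confounding after adjusting for *estimated*
(rather than true) AGV inflates the null association χ² by a term that
decays like 1/M in the panel size M, and at M = 24 000 the measured
inflation is within Monte-Carlo error of none. The panel is held in
float32; it exists only to estimate AGV.

Causal-SNP replicates are drawn retrospectively: per population with
frequency f and log-odds ratio β, controls sample genotypes from
Hardy–Weinberg proportions at f and cases from probabilities
∝ HWE(g)·exp(βg) — the rare-disease approximation. An exact-prevalence
option (intercept solved so the population prevalence matches, default off)
is available via `SimulationScenario.prevalence`. The phenotype vector is
fixed by the scenario (case counts per population), so the no-variant null
model is fitted once per scenario and reused across replicates.

Heterogeneity models assign per-population log-odds ratios from a single
magnitude b: `null` (0), `homogeneous` (+b), `african_specific` (+b in
the four African populations), `african_vs_others` (+b African, −b
others), `eastasian_vs_others` (+b East Asian, −b European/South
Asian/Hispanic, 0 African). Structure levels fix case fractions per
ancestry block at constant total sample and case counts: none = 0.5
everywhere; moderate = 0.35 (African), 0.65 (East Asian), 0.45 (South
Asian), 0.55 (Hispanic), 0.65 (European); extreme = 0 in the African
populations and 5/6 elsewhere. The moderate gradient and the uniform
non-African extreme fraction are this package's choices, constrained by
the design requirements (fixed totals; no African cases under extreme).

Randomness: a single master seed feeds `numpy.random.SeedSequence`
substreams — one for the background cohort, one per replicate — so results
are bit-reproducible and independent of execution order. Default 1000
replicates per scenario; rejection proportions carry binomial Monte-Carlo
SEs, and the genome-wide 5×10⁻⁸ threshold is reported but unreliable below
~10⁷ replicates.

## What the generator does and does not emulate

It reproduces continental allele-frequency differentiation, individual
admixture, phenotype-ancestry confounding, and per-ancestry effect
heterogeneity — the ingredients that drive type I error and power of the
tests. It does not simulate LD (SNPs are independent), X chromosomes,
multi-SNP architectures, genotyping error or imputation noise. Passing
tests therefore demonstrate the statistical properties of the tests under
structure and heterogeneity, not robustness to LD-driven or
technical artefacts in real data.

## Problem sizes used in the checks

The end-to-end suite runs one shared 20 000-sample cohort with the
24 000-SNP panel; calibration uses 3000 null replicates (5000 in
`scripts/acceptance.py`), and each power cell of the
model×structure×effect grid uses 500 replicates with |log OR| in
{0.1, 0.2, 0.3, 0.4} — enough for 3-SE Monte-Carlo comparisons of
rejection proportions while keeping a full run in the minutes range on a
single CPU.

## Known limitations

* Residual type I error inflation of the 1-df association test under
  extreme structure decays as 1/M in the background-panel size but is
  never exactly zero with estimated AGV; at the default panel it is below
  Monte-Carlo resolution.
* The 2-df interaction test is mildly anti-conservative at nominal
  thresholds under this replicate design (empirically ~0.06–0.09 rejection
  at the 0.05 level with homogeneous effects), independent of the panel
  size. The cause is the design, not the panel: each replicate re-draws
  the causal allele frequency *per population*, so genotypes are
  exchangeable within a population rather than independent. For the main
  effect this extra variance cancels — the null model's score equations
  zero the residual sum in every direction the AGV span, and the fitted
  probabilities match the per-population case fractions — but the
  interaction score weights residuals by g·x₁, and the per-population
  residual×axis sums are not constrained to zero by the null fit, so the
  between-replicate frequency variance leaks into the statistic. Cochran's
  Q, built from per-population fits that condition on each population's
  own frequency, is immune. At genome-wide significance the bias is
  invisible, which is where the heterogeneity claims live; treat nominal
  P_het values near 0.05 from cohort-style retrospective simulations with
  corresponding caution.
* Cochran's Q is the plain statistic without small-sample corrections;
  populations that are monomorphic or single-class for a variant are
  dropped from its meta-analysis with a reason code.
* The exact-prevalence sampler assumes a common prevalence target across
  populations; per-population prevalences are not modelled.
* Dosage-based (imputed) analysis is supported in I/O and testing, but the
  simulation engine draws hard genotypes.
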
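# Methods

## Model and assumptions

A proband-parent trio with phased parental genotypes determines, over a
cis-window, four possible offspring genotypes: each joins one whole
paternal haplotype with one whole maternal haplotype. The package assumes
**no crossover within the cis-window** — reasonable because expression
imputation models use only local (cis) predictors, so a window spans at
most ~1 Mb — and **correct phasing**. Under these assumptions exactly one
configuration reproduces the proband's genotype; `check_mendelian_consistency`
reports families where none does (phasing error or within-window crossover),
and such families are flagged and dropped from per-variant tests.

Imputed expression is the linear score x = Σⱼ wⱼ dⱼ over harmonized
predictor dosages. Linearity gives two exact identities used throughout as
invariants: the four configuration values sum to 2 × (father + mother), and
the single non-transmitted sibling's value equals father + mother − proband.

The association test is conditional logistic regression on matched sets of
one case (proband) and K controls: K = 3 retained pseudo siblings
(default), K = 2 parents (parent-control design), or K = 1 non-transmitted
sibling (conditional variant of the one-sibling design). Conditioning on
the set removes all family-level confounding (any per-family constant
cancels), which is what makes the design robust to population
stratification. At β = 0 every family contributes probability 1/(K+1), so
the null log-likelihood is −N·ln(K+1) exactly — used as a self-check.

The exclusion step removes the configuration with imputed expression
closest to the proband's (absolute difference; sum of squared differences
across genes in the multivariate fine-mapping case, computed on per-gene
normalized values so no gene dominates). Ties are broken toward the lowest
configuration index in the fixed order (1,1), (1,2), (2,1), (2,2) —
deterministic and seed-free.

## Estimation and numerical choices

- Newton-Raphson with step-halving (a step is halved until the
  log-likelihood does not decrease); convergence when max |score| < 1e-8;
  at most 50 iterations; non-convergence is reported, never silent.
- Standard errors from the observed information at the optimum; two-sided
  p-values from the normal approximation to z = β/SE.
- **Separation**: declared when the case exposure is the strict extremum in
  every informative set, or when |β| exceeds 15 on the standardized scale.
  β is then capped at ±15 and the p-value falls back to the score test at
  β = 0, which remains valid under separation. The one-sibling
  *unconditional* design is the exception: it mirrors a plain GLM fit and
  reports the Wald result as-is (flagged), so under quasi-separation its SE
  inflates and power is lost — this behavior is intentional, and is what
  drives the design's poor performance in small ascertained cohorts (see
  the power comparison below).
- Uninformative sets (all K+1 exposures identical) contribute a constant
  and are dropped; both total and informative family counts are reported.
- Multivariate fits monitor the information-matrix condition number;
  above 1e8 a ridge term (1e-6 × trace/q) stabilizes the step and the
  result is flagged for collinearity. This arises when co-localized genes
  share predictors in strong LD.
- Exposures are z-scored per gene/tissue/cohort over probands plus
  retained pseudo siblings with the population-SD convention (divide by n),
  so β is per SD of imputed expression. Standardization is affine and the
  conditional-likelihood z-statistic is invariant to it (verified
  numerically); raw-scale fitting is available by config. Zero-variance
  groups yield an NA row flagged "uninformative".
- Permutation p-values use (r+1)/(B+1); the uncorrected proportion is
  available behind a flag.

## Harmonization and data conventions

VCF positions are 1-based; region strings are 1-based inclusive; the
variant key is (chrom, pos, ref, alt). Multiallelic records and records
with any unphased or missing call are skipped with counts. Weight tables
use one TSV dialect (gene, tissue, feature_type, cluster, chrom, pos, ref,
alt, effect_allele, weight). When the effect allele is the reference
allele the dosage is complemented (d → 2−d) at scoring time.
Strand-ambiguous (A/T, C/G) predictors are dropped by default. A gene is
skipped when more than half of its total |weight| mass is lost to missing
predictors (configurable). PRS scoring reuses the same harmonization and
linear-scoring path.

Meta-analysis: fixed-effect IVW (weights 1/SE²) across trio cohorts;
sample-size-weighted z combination (weights √N, N = informative families)
when a replication stage provides only z-scores; the two-stage pipeline
chains them. BH adjustment within tissue; a cross-tissue Bonferroni cutoff
uses a configurable total test count. The pTDT divides (proband −
midparent) by the sample SD (n−1) of midparent scores and applies a
one-sample t-test.

Mutation classes follow a controlled vocabulary (LoF: frameshift,
stop-gained/lost, splice donor/acceptor and their near-splice variants;
missense and synonymous with near-splice variants); deleterious missense
requires MPC strictly greater than 2. Expected de novo counts are
2 × n × Σμ by default (two chromosome copies per offspring; factor
configurable because conventions differ across mutability tables).

## The synthetic generator

The simulator emulates: phased parental haplotypes with i.i.d.
Bernoulli(MAF) alleles (default MAF 0.3, 5 SNPs per window), Mendelian
transmission of one whole haplotype per parent, a linear weight model with
weights rescaled so the genetic expression value has unit variance (effects
are per-SD), optional environmental noise N(0, σ²) added before disease
assignment, and the logistic disease model
P(D=1) = 1/(1+exp(−β0 − β1·G)). Two disease modes: Bernoulli draws, and
the deterministic threshold rule D = 1 iff P > 0.5. The two intercepts
studied are β0 = 2.25 (baseline prevalence 0.905) and β0 = −2.5 (0.076).
Ascertainment resamples until the requested number of affected probands is
reached, as trio studies sample through an affected child. All randomness
flows from one root seed through named substreams, so every generator is a
pure function of (config, seed).

Not emulated: LD between SNPs, realistic MAF spectra, within-window
recombination, phasing error, genotyping error, covariates, and sibling
environmental correlation. Passing tests therefore demonstrate the
statistical behavior of the *method* under its own assumptions, not
robustness to those data features.

## Simulation experiments and sizes

- **Shuffled-status type-I error**: 2,000 genes × 300 ascertained trios;
  within each matched set the case label is reassigned uniformly, making
  members exchangeable; rejection at α = 0.05 should track α and p-values
  should be KS-uniform.
- **Noise robustness**: one ascertained cohort (400 trios, β1 = 0.25,
  β0 = −2.5); noise variances 0.05 to 1 in steps of 0.05, 100 replicates
  each, noise added to every member's exposure before refitting. Power
  declines with σ². The null arm (β1 = 0) redraws the cohort every
  replicate (`refresh_dataset`): with a single fixed cohort the replicates
  share the base data and the *conditional* rejection rate can sit far from
  α for any one cohort, which is a property of the design, not inflation.
- **Power comparison**: 1,000 trios per replicate, 200 replicates, the
  threshold disease rule, analyzing affected families with all three
  designs at α = 0.05. Effect grids keep each regime informative:
  β1 ∈ {1.0, 1.25, 1.5} at β0 = −2.5 (a handful of affected trios per
  replicate) and β1 ∈ {0.5, 1.0, 1.5} at β0 = 2.25. At high prevalence
  parent controls underperform both pseudo-sibling designs (parents of
  affected children in a common disease carry much of the risk themselves);
  at low prevalence the one-sibling GLM underperforms the three-sibling
  conditional fit (quasi-separation in small ascertained samples inflates
  its Wald SE). Realized affected counts are reported rather than assumed.
- **Coverage**: 200 replicates of 1,000 ascertained trios, true β = 0.3
  per SD, β0 = −4. The conditional-likelihood estimand equals the
  generative log-odds effect in the rare-disease limit, where the logistic
  risk is well approximated by the exponential; at common-disease
  intercepts the estimator is mildly attenuated, which is why the coverage
  experiment uses a rare-disease intercept.

These sizes make the whole experiment battery run in a few minutes on one
CPU while keeping Monte-Carlo error well below the effect sizes being
compared.

## Known limitations

- The no-crossover and perfect-phasing assumptions are structural; real
  cohorts violate them at low rates and the Mendelian-consistency report is
  the intended diagnostic.
- The one-sibling design's default is the unconditional GLM; a 1:1
  conditional variant is available, and the two genuinely differ in small
  samples. The default is documented rather than resolved.
- The cross-tissue significance cutoff depends on a total-test count that
  is a configuration input, not something the package can infer from a
  partial result table.
- Stratified-analysis permutation uses the β ratio between two groups and
  is undefined when a group's fit fails; such groups return NA.
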
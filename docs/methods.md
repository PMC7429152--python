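# Methods

This note documents the models implemented in `copdprs`, the synthetic
study conditions, the numerical choices, and the limits of what the tests
demonstrate.

## Summary-statistic penalized regression

The weight derivation works entirely from GWAS summary statistics plus a
reference LD matrix. Each variant's two-sided p-value and effect sign are
converted to the marginal SNP–trait correlation r = sign·t/√(n−2+t²), with
t the upper-tail t quantile at p/2 on n−2 degrees of freedom (p=1 maps to
r=0; p=0 is rejected upstream as malformed). The weights minimize

    f(β) = ½ βᵀ[(1−s)R + sI]β − rᵀβ + λ‖β‖₁,

with R block-diagonal (zero LD assumed across blocks). Since diag(R)=1 the
regularized quadratic has unit diagonal and coordinate descent needs no
per-coordinate denominator: βⱼ ← soft(rⱼ − (1−s)·Σ_{k≠j}R_{jk}βₖ, λ).
λ is the soft-threshold level on the correlation scale.

Numerical choices: convergence when the largest coordinate change in a
sweep is below 1e−5 (tol configurable); at most 1000 sweeps, after which a
convergence error carries the last iterate; warm starts along the
descending-λ path during tuning. At s=1 the solution is the closed-form
soft threshold and one sweep suffices. The test suite checks the
subgradient optimality conditions at the returned solution and agreement
with an independent bound-constrained QP minimizer on random small blocks.

## LD reference

Within-block Pearson correlations of mean-imputed, standardized reference
dosages; correlations across blocks are taken as zero. A diagonal ridge of
1e−8 (renormalized so the diagonal stays exactly 1) guarantees positive
semidefiniteness under finite panels. Zero-variance variants are excluded
from their block and logged. Block boundaries are fixed-size windows
(default 100 variants; tests align them with the simulation's true blocks).
Reproducing human recombination-derived block maps is out of scope.

## Hyperparameter tuning and the combined score

The grid defaults to s ∈ {0.2, 0.5, 0.9, 1} and 20 log-spaced λ in
[0.001, 0.1]. The tuning metric is the squared correlation of the raw score
with the corresponding trait in the tuning cohort; an AUC-against-COPD
metric is available by configuration. Because an individual lung-function
score is *protective* for COPD, its raw AUC sits below 0.5; the AUC metric
therefore ranks grid points by folded discrimination max(AUC, 1−AUC),
which is direction-free. Which of the two objectives the original workflow
used is not documented anywhere authoritative; both are provided and the
trait-R² default is a package choice. Exact metric ties resolve toward the
larger λ (sparser model).

The two trait scores, standardized within cohort, are combined with the
coefficients of a logistic regression of COPD on both scores fitted in the
tuning cohort; the combined score is re-standardized per cohort, which
makes the logistic intercept irrelevant to all downstream analyses. An
unweighted sum and externally fixed coefficients are also supported. If the
two inputs are numerically collinear (|r| > 0.9999) the fit would be
singular; the package warns and splits a single-score coefficient equally
instead.

## Synthetic study conditions

The generator's defaults define the study and are not adjusted per
analysis:

- Genotypes: dosage = sum of two independent haplotypes, each a latent
  standard Gaussian thresholded at the MAF quantile; latent correlation is
  first-order autoregressive within 10-variant blocks (adjacent ρ = 0.5 by
  default) and zero across blocks. MAF ~ U(0.05, 0.5). Haplotype-copying
  models, imputation error and chip ascertainment are deliberately not
  emulated.
- Genetic architecture: 20% of variants causal; their (FEV₁, FEV₁/FVC)
  effects are bivariate Gaussian with correlation 0.7. The architecture
  (causal set, effects, MAFs) is drawn from a separate architecture seed so
  that training, panel, tuning and test cohorts share one genetic model
  while individuals differ.
- Traits: standardized trait = genetic score (scaled to h² = 0.4 by
  default) + environment. The environmental part allocates 20% of its
  variance to standardized pack-years (so smokers have worse lung function
  while the genetic score stays uncorrelated with smoking) and correlates
  0.3 across the two traits. FEV₁ %predicted = 90 + 13·z; FEV₁/FVC
  = 0.73 + 0.06·z (clipped to [0.2, 0.95]) — means/SDs chosen to give a
  smoking-enriched-cohort COPD prevalence near 13% and realistic PRISm and
  GOLD occupancy. Absolute FEV₁ uses a configurable linear reference
  equation in height, age and sex; published prediction equations are not
  reproduced.
- Pack-years: zero-inflated gamma (30% never-smokers; Gamma(shape 2,
  scale 15) otherwise), independent of the genetic score by construction.
- Categories: COPD = FEV₁/FVC < 0.7 and FEV₁ < 80% predicted. PRISm =
  ratio ≥ 0.7 with FEV₁ < 80%. With obstruction, GOLD 1/2/3/4 at FEV₁
  ≥80 / 50–79 / 30–49 / <30 % predicted (standard GOLD boundaries).
- Secondary phenotypes: a latent severity correlates with the genetic
  *liability* (negative of the FEV₁ genetic score) by `prs_link`
  (default 0.3). Continuous imaging measures are linear in it; %LAA<−950
  and gas trapping are log-normal; local-histogram percentages are
  max(latent, 0), giving genuine zero-censoring; visual grade and CT
  subtype discretize the latent. Exacerbations depend only on lung
  function (a fully mediated pathway), so genetic associations with them
  should vanish after adjusting for FEV₁ and FEV₁/FVC — the qualitative
  pattern the evaluation reproduces. Lung growth crosses a reduced-growth
  latent (loading 0.4 on the FEV₁ genetic score) with an independent
  early-decline latent into four patterns. The exacerbation and severity
  link functions are stand-ins: nothing calibrates them to measured
  exacerbation epidemiology.

Default problem sizes (training GWAS n = 5000 with m = 1000 variants,
LD panel n = 500, tuning n = 2000, two test cohorts of n = 4000) keep a
full run in seconds while leaving every estimator comfortably powered.
Because 1000 variants at h² = 0.4 are tagged far more tightly than 2.5M
SNPs in a real genome, absolute effect sizes (OR per SD around 4, decile
ORs in the tens) are much larger than human-cohort values; passing tests
demonstrate the machinery recovers its own generating model, not that the
synthetic effect sizes transfer to real data.

## Evaluation and epidemiology

- OR per SD: logistic regression of COPD on the standardized score plus
  covariates (default age, sex, height, pack-years, principal components
  where present); Wald CIs; perfect separation raises an error naming the
  offending term.
- Deciles: rank-based bins with ties in the lower bin; a constant score is
  a degenerate-quantile error. Decile ORs come from 2×2 counts against the
  reference (lowest decile or middle tertile); zero cells get the
  Haldane–Anscombe 0.5 correction and a flag.
- AUC: midrank Mann–Whitney statistic (exactly concordant-pair counting
  with ties at ½); variances and correlated-curve comparisons by DeLong's
  method — the de-facto standard behind published AUC comparisons, adopted
  here as an assumption since the comparison test is rarely named. The
  Bonferroni threshold 0.005 for ten subpopulation comparisons is reported,
  not enforced.
- Youden cutoff: maximizes sensitivity+specificity−1 over observed
  thresholds; ties break toward higher specificity (a screening context
  favors fewer false positives); PPV/NPV from the confusion table.
- Meta-analysis: inverse-variance fixed effects; DerSimonian–Laird τ² for
  random effects (reduces exactly to fixed effects when Q ≤ k−1); Cochran
  Q and I² = max(0, (Q−(k−1))/Q)·100. AUC pooling also supports
  effective-sample-size weights n_eff = 4/(1/n_cases + 1/n_controls); the
  pooled SE uses supplied per-study (DeLong) variances, or Hanley–McNeil
  variances from counts when none are given — the ESS-weighted SE has no
  canonical definition, so this one is documented as the package's.
- Attributable risk: RR from the 2×2 table; AR% = 100(RR−1)/RR; Levin
  PAR% = 100·p_e(RR−1)/(1+p_e(RR−1)), cross-checked at runtime against
  excess-case counting (they are algebraically identical). Targeted impact
  assumes complete exposure removal in a decile stratum: removed cases =
  exposed cases in stratum × AR%/100, reported as a percent of all cases.

## Secondary-phenotype models

- Linear models per SD of the score, with optional log transform; zeros
  under the log receive an offset of half the smallest positive value
  (configurable, flagged) — the handling of zeros under published log
  transforms is not standardized, so the choice is explicit.
- Tobit: left-censored Gaussian likelihood maximized by BFGS on
  (β, log σ) with analytic gradients, initialized from OLS on the
  uncensored subset; standard errors from the inverse observed information
  (numerical Hessian); σ's SE by the delta method. A fit is rejected if
  the gradient norm at the optimum is not negligible. With no censoring
  the MLE coincides with least squares, which the tests verify.
- Ordinal: proportional-odds logistic (statsmodels `OrderedModel`), OR per
  SD of being in a higher category; with two categories it reproduces
  binary logistic regression exactly, and reversing the category order
  flips the coefficient sign — both used as oracle checks.
- CT subtypes: one logistic fit per subtype against the normal-imaging
  reference, restricted to the two groups; CIs widened to level
  1 − 0.05/n_comparisons; the 0.0025 family threshold for twenty imaging
  phenotypes is reported in the interface constants.
- GOLD/PRISm contrasts: Welch two-sample tests on mean score (the
  comparison test is a package choice; published analyses rarely name
  theirs).
- Growth patterns: reduced (reduced-normal + reduced-early) vs normal
  (normal-normal + normal-early) logistic regression, adjusted for age,
  sex, height, baseline FEV₁, bronchodilator response and airway
  hyper-responsiveness.

## Pipeline

Eight stages (simulate, build, score, combine, evaluate, meta, epi, pheno)
run from a validated YAML/dict config with defaults injected and unknown
keys rejected at their JSON-pointer path. Stage seeds derive
deterministically from the global seed; outputs are plain-text TSV/JSON
under the run directory with SHA-256 hashes in a manifest; identical
configs reproduce identical hashes. Standardization of scores is always
within-cohort, never pooled.

## Known limitations

No realistic human LD maps, population structure (beyond supplied PC
covariates), rare variants, or non-additive effects; no liftover or
INFO-score recomputation; no time-to-event or longitudinal decline
modelling; no reclassification or calibration metrics. Strand-ambiguous
palindromic variants are dropped rather than frequency-resolved — the
conservative default where allele frequencies cannot arbitrate. The
meta-analysis of Tobit coefficients pools latent-scale βs with
inverse-variance weights and is labeled as such.
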
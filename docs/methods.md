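# Methods

## Model

All tests condition on a logistic null model for a binary outcome
(e.g. hypertension) with covariates,

    logit P(y_i = 1) = x_i' beta,        x_i = (1, AGE_i, SEX_i, ...)

and ask whether genotype dosages g_i in [0, 2] (possibly fractional
after imputation) improve it.  Analyses use complete cases; dosage
missingness is mean-imputed per variant by the CLI (with a notice).

M̃AC — the number of individuals with dosage strictly greater than
zero — is the sparsity measure used for pooling and reporting; with
fractional dosages it is a proxy for the minor allele count.

## Single-variant tests

- **lrt** — standard likelihood-ratio test, chi-square(1) reference.
- **plrt** — penalized likelihood-ratio test.  The Firth penalty adds
  `0.5 log |i(beta)|` (Jeffreys prior) to the log-likelihood, which
  keeps estimates finite under complete/quasi-complete separation; for
  a 2×2 table the slope equals Haldane's add-one-half log odds ratio
  exactly.  The constrained fit used for the test statistic maximizes
  the penalized likelihood of the FULL design with the tested
  coefficient pinned (profile convention), so the statistic is
  nonnegative by construction.  IRLS with step damping is polished by a
  BFGS fallback on near-flat ridges (tiny separation margins).
- **score** — standard score test, U²/V against chi-square(1), with
  the genotype residualized against the covariates.
- **score-var** — rescales the statistic by the exact fourth-moment
  variance of the quadratic form under Bernoulli sampling,
  `sigma_Q^2 = 2 V^2 + sum_i g_adj,i^4 (s_i - 6 s_i^2)`,
  where `s_i = pi_i (1 - pi_i)`.
- **score-var-kurt** — the full small-sample adjustment.  The p-value
  is a two-sided Lugannani–Rice saddlepoint approximation to the exact
  null law of U conditional on pi-hat_0 (the B → ∞ limit of the
  parametric bootstrap), built on the exact Bernoulli cumulant
  generating function `K(s) = sum_i [log(1 - pi_i + pi_i e^{a_i s}) -
  s a_i pi_i]` with `a = g_adj`.  This reference is accurate in both
  bulk and tail; the more familiar kurtosis moment map `(Q - mu) /
  sigma * sqrt(2 df) + df` against chi-square(df) with
  `df = 12 / gamma-hat` is a shifted-gamma fit whose support floor
  `mu - sigma sqrt(df/2)` is positive at most variants, so every Q
  below the floor collapses to p = 1 exactly — an atom of several
  percent of null p-values that ruins bulk uniformity while barely
  helping the tail.  The moment quantities are still computed and
  reported as diagnostics: mu_Q = V, the exact sigma_Q above, and
  gamma-hat either estimated by parametric bootstrap
  (y* ~ Bernoulli(pi-hat_0), B >= 1000 enforced, `moments="bootstrap"`)
  or, preferably, computed exactly from the Bernoulli cumulant
  recurrence `kappa_{r+1} = p(1-p) d kappa_r / dp` up to order 8
  (`moments="analytic"`; this is what the simulation driver uses), with
  `df = 12 / gamma-hat` (floor 0.5, cap 1e5; gamma-hat → 12 in the
  large-sample limit gives df = 1).  Everything conditions on
  pi-hat_0 (no per-replicate covariate refit); this is an
  approximation, documented and tested against full resampling oracles.

## Variant-collapsing tests

Variants are grouped into K equal-count subregions by position
(default K = 6) and optionally restricted by MAF class (rare < 0.01,
low-frequency 0.01–0.05, common > 0.05; class sets `rare`, `rare_lf`,
`all`).  Weights default to the Beta(1, 25) density in MAF,
`w_j = 25 (1 - maf_j)^24`; Madsen–Browning `1/sqrt(n p (1-p))` is
available.

- **burden** — score test of the weighted dosage sum.
- **skat** — `Q = r' G W^2 G' r` with null residuals r; the reference
  is the eigenvalue mixture of chi-squares of the projected kernel,
  evaluated by the quadratic-form engine below.
- **skato** — `Q_rho = (1 - rho) Q_skat + rho Q_burden` over a rho
  grid (default 0, 0.1^2, ..., 1); the minimum-p statistic's null
  distribution follows the standard decomposition into a common
  one-degree component plus a rho-dependent mixture, integrated
  numerically (48-node Gauss–Legendre on [0, 7] after transforming the
  common component).  Inside that integrand the conditional remainder
  tail uses the Liu moment approximation rather than full inversion:
  the integrand is evaluated ~50 times per rho grid and the inversion
  would dominate the runtime while changing the integral by less than
  the quadrature error in the regimes tested.  The final p is capped
  at `min_p * |grid|` (Bonferroni) from below by the minimum p.

**Small-sample adjustment** — with `small_sample="auto"` (default) the
moment adjustment activates when n < 2000 or the case fraction is
below 0.2: the chi-square-mixture reference is replaced by a
mean/variance/kurtosis match (`(Q - mu)/sigma * sqrt(2 df) + df`
against chi-square(df), df = 12/kurtosis), with moments estimated from
a parametric bootstrap (B = 10,000 default).  All
bootstrap draws within one replicate share the resampled y* so method
comparisons are paired.

## Quadratic-form engine

`davies_pvalue` inverts the characteristic function of
`sum lambda_j chi2_{df_j}`: the integrand `sin(theta(u)) / (u rho(u))`
is integrated with 10-point Gauss–Legendre panels of width
`pi / (omega + A'(0))` — at most half an oscillation per panel — in
vectorized blocks, stopping when an analytic bound on the remaining
tail certifies the requested absolute accuracy (default 1e-9; a fault
flag reports failure instead of silently degrading).  Mixtures whose
weights coincide numerically are merged into multi-df components and
single-component mixtures use the exact scaled chi-square tail.
`liu_pvalue` provides the moment-matched noncentral chi-square
approximation used as fallback and for quantile starting points.

## Synthetic cohort generator

`default_panel_spec` builds a ~90-variant exonic-style panel: six
subregions of unequal size, MAF spectrum dominated by rare variants
(81 rare / 5 low-frequency / 4 common), a 4-variant tight LD block
(equal MAF 0.008, pairwise r² > 0.7, spanning < 30 bp) generated from
a shared latent haplotype, and functional variants (about a quarter)
with alternating-sign effects `|beta_j| = c |log10 maf_j|`, c = 0.75 —
rarer variants get larger effects, and the sign alternation makes the
burden/SKAT power contrast structural rather than incidental.  The
scale c = 0.75 places region power at alpha = 0.05 in the mid-range
(neither floor nor ceiling) for n ≈ 2000.  Phenotypes: covariates (AGE, SEX) are drawn once per
cohort; null replicates re-draw outcomes from the covariate-only
model with a fixed case count (prevalence 0.178); alternative
replicates add the genotype effects with an intercept calibrated to
keep the same prevalence.  A configurable fraction of samples has
missing covariates (complete-case analysis mirrors the n = 1943 /
1862 complete-case structure of the motivating design).

## Evaluation driver

`run_replicates` fixes genotypes, re-draws phenotypes R times
(replicate r uses seed `(base_seed + r) mod 2^31`, so any replicate
regenerates in isolation bit-for-bit), and runs the configured tests
on the complete-case subsample through a batched IRLS engine.
Summaries: pooled type-1 rates by M̃AC (band half-width
`2 sqrt(alpha (1 - alpha) / N)`, i.e. ±2 binomial SEs), power per
target and class, QQ points, Bonferroni adjustment.

## Known limitations

- The moment-matched references (score-var and the small-sample
  collapsing adjustment) are **tail approximations**: they calibrate
  rejection probabilities at small alpha.  In the bulk of the null
  distribution (p ≳ 0.2) their absolute error can reach a few
  hundredths, and for a variant with very few integer-dosage carriers
  the resampling law is a handful of atoms that no continuous
  three-moment fit can match closely.  Resampling-oracle agreement is
  therefore asserted in the deep tail (oracle p ~ 1e-3), the regime
  the adjustments target.  The saddlepoint reference used by
  score-var-kurt is continuous by construction; at variants whose
  score distribution is strongly atomic it is mildly conservative
  (it smooths across the atoms) but has no p = 1 pile-up.
- The parametric bootstrap holds the null fitted probabilities fixed;
  refitting covariates per replicate would be more faithful and more
  expensive.
- The SKAT-O omnibus integrand uses the Liu tail for the conditional
  remainder (see above); single-rho grids bypass the integration.
- The generator's LD block is a single haplotype construct — it is not
  a general LD simulator.
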
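# Methods

## Standardization and ecological indices

Expected counts use *internal* indirect standardization.  Five adjustment
strata are carried throughout: 18–24, females 25–39, males 25–39, 40–54 and
55+ (the reference).  The catchment-wide prevalence of stratum *g* is
`p_g = C_g / N_g` (cases over persons at risk, pooled over areas), and
`E_k = sum_g n_kg p_g`.  Because the `p_g` come from the same data,
`sum_k E_k = sum_k y_k` holds exactly; the package asserts it to 1e-9.
The prevalence rate ratio is `y_k / E_k`, with `E_k = 0` and cases present
reported as an infinite (flagged) ratio.

A note on the packaged catchment aggregates: the stratum populations of the
aggregate table sum to 126 893, while the study-level bookkeeping total of
adults at risk is 109 397 (the sum of the two constituent cities, and the
denominator of the crude prevalence 358/109 397).  The two totals are
inconsistent in the source material.  The package keeps both as printed and
never mixes denominators: prevalence cells are computed from the table's own
populations, bookkeeping quantities from the city totals.

Ecological indices are composites of two per-area proportions, each
standardized to a Z-score across areas and summed.  Z-scores use the
population SD (`ddof=0`): the areas are the complete set of units, not a
sample; the convention only matters through the SD = 1 invariant and is
applied consistently.  Prevalence confidence intervals, where requested, are
Wilson score intervals — a deliberate choice for small stratum counts; only
point prevalences are asserted anywhere.

## Frequentist stage

Poisson fits are IRLS maximum likelihood (via statsmodels GLM) with the log
population as offset; the negative binomial is NB2 (variance
`mu + mu^2/theta`) with `theta` estimated jointly by ML and counted as a
parameter in the AIC.  When the NB dispersion diverges (data effectively
Poisson) the fit is reported as equidispersed with `theta` capped at 1e4 and
Poisson coefficients.

Dean's score statistic for overdispersion is the unadjusted variant

    P_B = sum[(y_k - mu_k)^2 - y_k] / sqrt(2 sum mu_k^2),

one-sided against N(0, 1).  Two conventions coexist deliberately: the
`decision` field reproduces the applied "statistic > 1.96" display rule,
while `p_value` is the one-sided tail, which is what calibration studies
should threshold.  The statistic evaluated at fitted means of a
p-parameter model is biased downward by roughly `-p·mean(mu)/sqrt(2 sum mu^2)`
(the fit absorbs variance), noticeable at 56 areas; null calibration in the
test suite therefore fits the true intercept+offset model.

Moran's I uses binary (not row-standardized) weights on Pearson residuals
of the best frequentist fit by default.  Both an analytic p (Cliff–Ord
randomisation moments, one-sided) and a permutation p (default 999
permutations) are available; the permutation p drives decisions when
requested.  The implementation is verified against a literal double-loop
evaluation to 1e-12.

Forward selection starts from the confounders-only design and adds the best
candidate per round only on *strict* criterion improvement, ties resolved
toward the smaller model; non-converged candidate fits are recorded and
skipped.  The same generic routine drives AIC selection for the GLMs and
DIC selection for the CAR models.

## CAR models and the sampler

The four random-effect structures (IND, IAR, BYM, LER) share the Poisson
likelihood and differ in the field prior; see the README table.  Priors
default to `beta ~ N(0, 1e5)`, `tau2, sigma2 ~ InverseGamma(1, 0.01)`,
`rho ~ Uniform(0, 1)` — the weakly-informative conventions of the disease-
mapping ecosystem — and are overridable per fit.  Variances and `rho` can
also be pinned (`*_fixed`), which is how the limit checks (LER at rho 0/1)
and degenerate-prior experiments are run.

Sampler design:

* **beta**: joint random-walk Metropolis whose proposal covariance is the
  Poisson ML covariance (Cholesky factor), scaled adaptively.
* **phi**: single-site random-walk Metropolis, vectorised over the colour
  classes of a greedy proper colouring of the adjacency graph — sites of
  one colour are conditionally independent given the rest, so a whole
  colour is proposed and accepted elementwise at once.
* **sum-to-zero constraint**: after each field sweep, `phi` is recentred
  and its mean transferred into the intercept (likelihood-invariant).  This
  identifies the level of the improper IAR prior and keeps the proper
  Leroux prior on the same convention; accordingly the variance updates use
  rank `n - 1` and the Leroux determinant excludes the null mode.
* **variances**: conjugate inverse-gamma Gibbs draws.
* **rho**: logit-scale random-walk Metropolis with the exact
  log-determinant `sum_i log(rho*lam_i + 1 - rho)` from the pre-computed
  nonzero spectrum of `D - W` (O(n) per proposal).
* **amplitude move**: at low counts the (field, variance) posterior is
  funnel-shaped and site updates traverse field amplitude slowly.  A joint
  rescaling `phi -> c·phi`, `tau2 -> c^2·tau2` with log-normal `c` fixes
  this; the CAR prior exponent is invariant under the map and the rank
  terms cancel, leaving
  `log alpha = dloglik + (2 - 2(a+1)) log c - (b/tau2)(c^-2 - 1)`.
* **adaptation**: proposal scales adapt every 100 sweeps toward acceptance
  0.35 (blocks) / 0.45 (sites) during burn-in only and are frozen afterwards
  to preserve detailed balance.  A warning is issued if a final acceptance
  rate leaves (0.05, 0.95).

The sampler was validated three ways: (i) against dense numerical
integration of the exact posterior on a 3-area toy (Gauss–Hermite over the
random effects, grid over the intercept); (ii) in an informative-data limit
(counts ~6500 per area) where the tau2 posterior must match the analytic
inverse-gamma conditional given the realized field — agreement to 3
decimals; (iii) against an independent general-purpose MCMC implementation
of the same Leroux model on weak data, which converges to the same
posterior while mixing roughly 8× worse per iteration.

Headline chain defaults are 20 000 burn-in, 10 000 retained, thin 10.  The
test suite and the acceptance script use scaled-down chains (typically
500–3000 burn-in, 1000–8000 retained, thin 1–5), sized so the full suite
runs in minutes; replicate counts in simulation tests (25–2000 depending on
the cost per replicate) were likewise chosen as the package's own balance
of statistical resolution against runtime.

DIC is `Dbar + p_D` with `p_D = Dbar - D(posterior means of beta and the
effect fields)`.  Geweke's Z compares the first 10 % and last 50 % of a
chain with spectral-density-at-zero variance estimates (Bartlett window,
lag ~ sqrt(segment length)); the package reports Z per scalar parameter and
a max-|Z| summary, since a single-number convergence claim is otherwise
ambiguous.  Hotspots are areas with `Pr(mu_k/E_k > 1 | data) > 0.75`.

## What the generator emulates — and what it does not

The generator reproduces: the areal scale (56 grid areas ≈ the 53-area
catchment; rook contiguity as the stand-in for irregular boundaries),
population sizes (lognormal, moments 2064/705, matching the published
range's right skew), age/gender composition (Dirichlet-multinomial around
the catchment shares, concentration 200), spatially smooth covariates
(proper CAR field, Z-scored), and counts from the exact model the analysis
fits, with defaults `beta_ECON = 0.12` (≈ the deprivation rate ratio 1.13
per SD), `rho = 0.8`, `tau2 = 0.3`, crude prevalence 358/109 397.  Cases
are stratum-tagged by within-area multinomial splits so that internal
standardization works exactly as it would with real stratum-level counts.

It does **not** emulate: age- or gender-dependent risk (stratum effects on
rates are zero, so confounder adjustment is exercised but never load-
bearing), irregular contiguity graphs, treated-prevalence selection
processes (care access, case leakage, institutionalisation), or spatial
covariate confounding beyond what the CAR covariate field induces.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the assumed model, not robustness to those real-data features.

## Known limitations (measured by the validation suite)

* **tau2 is weakly identified at realistic counts.**  With ~7 cases per
  area, per-area field values are seen through Poisson noise of comparable
  size; the posterior for tau2 is then dominated by a realization's
  effective field variance and by the InverseGamma(1, 0.01) prior, which
  concentrates near zero.  Frequentist coverage of the equal-tailed 95 %
  credible interval at a fixed truth tau2 = 0.3 measures ~0.82 over 50
  replicates (beta ~0.90, rho ~0.96).  This is a property of the posterior,
  not the sampler — see the validation points above.
* **DIC rarely separates the CAR structures at this scale.**  Expected DIC
  differences between IND/IAR/BYM/LER on 56 areas are of order 1–2, smaller
  than between-replicate noise; on Leroux-generated data the Leroux model
  attains the minimum DIC in only ~20 % of replicates, with wins spread
  over all four structures.  Structure choice by DIC on a single dataset of
  this size should be read as weakly informative.
* **Exceedance-based hotspot detection has an information ceiling.**  For a
  doubled risk on an expected count of 10, the observed count is
  Poisson(20), and even an unshrunk posterior flags the area (exceedance
  > 0.75) only when the draw is high enough — a ceiling near 0.9 before any
  shrinkage; the Leroux fit's shrinkage toward a flat field lowers measured
  sensitivity to ~0.5–0.7 depending on design, while false flags on null
  areas stay below 3 %.  Exceedance hotspot maps are conservative.
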
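# Methods

`socialprs` implements a two-stage analysis linking polygenic risk for
mental disorders to count-scored social behaviour in children, of the kind
run on large birth and twin cohorts with SDQ (Strengths-and-Difficulties
Questionnaire) subscales. Stage 1 estimates, per measurement occasion, the
association between a disorder polygenic risk score and an untransformed
0–10 social score. Stage 2 treats those per-measure estimates as data and
asks what moderates them: age at assessment, reporter, social trait,
cohort. Because restricted cohort genotypes are not distributable, a
synthetic-data module generates inputs with the statistical structure the
two stages assume, and every stage is validated against independent
oracles on that synthetic data.

## Stage 1: C+T scoring and negative-binomial association

**Scoring.** GWAS summary statistics (per-variant log-odds, SE, p,
frequency) are harmonized to the target panel's counted allele (sign flip
on swapped alleles; strand-ambiguous A/T and C/G variants dropped by
default), then greedily LD-clumped: the best remaining variant by
ascending p becomes an index and removes neighbours within a window whose
dosage r² exceeds a threshold. Defaults r² = 0.1, window = 250 kb are the
conventional C+T settings and are config-exposed; ties on p are broken by
smaller position then ID so the output is order-invariant. Scores are
sums of dosage × aligned effect over clumped variants passing a p-value
threshold P_T (nine defaults spanning 0.001 ≤ P_T < 1; P_T ≤ 0.1 is the
representative threshold used for stage 2), mean-imputed per variant when
dosages are missing, and Z-standardised over scored samples.

**Association.** Scores `y` in a single (cohort, age, reporter, trait)
cell are modelled as NB2: E[y] = exp(Xβ), Var[y] = μ + αμ², with the
likelihood maximised jointly over coefficients and dispersion (Newton,
with BFGS fallback; convergence flagged on the result). β is the change
in log counts per 1 SD of PRS. For twin cohorts a family-level Gaussian
random intercept is integrated by adaptive Gauss–Hermite quadrature
(8 nodes by default; the per-family mode is found by vectorised damped
Newton and the grid is centred and scaled there). At the lower bound of
the random-intercept SD the model reduces exactly to the fixed-effects
fit, which the tests exercise. Entering several disorder scores at once
gives the cross-disorder-adjusted fit; each effect's ΔMcFadden R²
compares the joint model against the model dropping that score, with the
null being intercept-plus-dispersion-only on identical rows. Replication
gates use one-sided p-values: p/2 when the estimate matches the reference
direction, 1 − p/2 otherwise.

**Multiplicity.** The effective number of independent measures M_eff is
the Li–Ji spectral count Σ [1(λ≥1) + (λ − ⌊λ⌋)] over eigenvalues of the
measure correlation matrix (Spearman by default — the scores are skewed
counts); Nyholt's variance-based estimator is available behind a flag.
Eigenvalues are rounded at 1e-9 before the floor because the estimator is
discontinuous at integers and exact-integer spectra (identity, all-ones)
must land exactly. Gates: two-sided α/(M_eff × score sets) for
discovery, (2α)/(M_eff × score sets) for one-sided replication, reported
to two significant figures; with the published effective counts (10 of
14 discovery measures, 12 of 15 follow-up measures, five disorders)
these give 0.001 and 0.0017. The stage-2 gate is α divided by the number
of disorders (0.05/5 = 0.01).

## Stage 2: mixed-effects meta-regression with a composite V

The labelled effects β (one per cohort × age × reporter × trait at the
representative threshold) follow the marginal model

    β ~ N(Xθ, V + τ²_cohort ZZ' + τ²_effect I)

X holds the intercept, age centred at 4 years, teacher-report and
peer-problem indicators, and optional cohort fixed effects. Z indicates
cohort membership — the "repeated measures nested within cohort" random
structure. V is the composite variance–covariance matrix: block-diagonal
by cohort with cov(β_i, β_j) = r_ij·SE_i·SE_j, where r_ij is the
phenotypic correlation between the two measures — the same construction
used for effect estimates with correlated phylogenetic histories. This
treats the phenotypic correlation as the correlation of the two estimates
computed on the same sample, which is the standard overlapping-samples
approximation; cross-cohort covariances are zero (disjoint samples). If
rounding makes V indefinite it is projected to the nearest PSD matrix
with the diagonal restored.

Variance components are optimised by bounded quasi-Newton on the log
scale with multi-starts at ~0 and a method-of-moments value (boundary
estimates at the floor are reported as 0); θ is the GLS solution at the
optimum. REML is used for reported coefficients, ML for likelihood-ratio
comparisons (fixed-effect LRTs are invalid under REML). With a single
cohort the two components are nearly aliased and only the effect-level
component is kept. The implementation reproduces `metafor::rma` to about
six decimals on a single-cohort diagonal-V fixture, and its optimum
matches a brute-force grid profile.

**Model pruning.** Backward elimination under ML: repeatedly drop the
moderator whose removal has the largest LRT p while that p > 0.05 (ties:
smaller |Z|), then refit by REML. The trace records every candidate test.
An optional retention override keeps a moderator whose removal lowers
model R² by more than a configurable amount (default 0.3, off by
default) — the analogue of retaining a borderline age effect that
captures a large share of effect heterogeneity. Moderators that
contribute no design columns (cohort with one level) are treated as
removable no-ops.

**Heterogeneity and explained variance.** Cochran's Q is the weighted
residual sum of squares under the fixed-effect weights V⁻¹, with
df = n_effects − n_coefficients. R² = 1 − τ²_total(model)/τ²_total(null),
the ratio of explained to total variance in the univariate effects,
floored at 0 and capped at 1. Predicted moderator profiles β̂ = Xθ̂ carry
CIs from the fixed-effect covariance; cohort-level empirical-Bayes
offsets (and their conditional variance) can be included.

## Power and genetic covariance

A normal-mixture model over m independent post-clumping markers: a
fraction 1−π₀ carries standardized discovery effects
b ~ N(0, h²/(m(1−π₀))), jointly normal with the target trait's effects
through the genetic covariance cov_gt; estimates add noise with variance
1/n_discovery, and a marker is selected when its Wald p passes P_T.
Truncated-normal second moments give the expected score–trait R², the
noncentrality n_target·R²/(1−R²), and power from the noncentral χ²(1).
Binary discovery traits are handled by converting liability-scale h² to
the observed scale with the standard ascertainment factor (prevalence and
case fraction supplied by the user). Two properties worth noting:

- Power at the *expected* covariance equals α exactly when cov_gt = 0,
  but a fully-marginal simulation with h²_target > 0 rejects more often —
  each replicate's random marker overlap gives a genuinely nonzero
  realized correlation. The Monte-Carlo validator therefore uses
  h²_target = 0 for the pure null and a moderate-power regime (where the
  expectation-level formula and the marginal simulation agree within
  binomial error) for the agreement check.
- Power is monotone in h² only under the fixed-covariance assumption
  (cov_gt proportional to h², "covariance equivalent to the SNP-h² of
  the disorder"); at fixed absolute covariance extra disorder-specific
  variance dilutes the shared signal and R² falls.

The covariance estimator inverts the same model: Gaussian likelihood of
observed standardized effects across thresholds around their
model-implied values, minimised over cov_gt within the Cauchy–Schwarz
bound, with a χ²(1) profile CI. The Monte-Carlo oracle simulates marker
effects and draws the target-sample correlation test exactly from its
2×2 Wishart distribution, so it shares no code path with the closed form.

## Pathway screen

For a baseline at P_T ≤ 0.1, each gene set's score restricts the
baseline clumped variants to those inside member-gene intervals ± flank
(default 10 kb; BED intervals are 0-based half-open, GWAS/VCF positions
1-based). There is no per-set re-clumping, so every pathway score is a
nested subset of the baseline — the property the screen logic relies on.
The regression specification is identical to the baseline fit, and a set
passes when p_pathway ≤ p_baseline ≤ gate (0.001). No competitive
permutation p-values are computed.

## Synthetic data

The generator emulates exactly what the stages assume, with one global
seed expanded into per-component substreams:

- **Genotypes.** Biallelic dosages in LD blocks with exchangeable
  correlation via a Gaussian copula on latent allele scores. Thresholding
  attenuates latent correlation at the dosage level, so the latent ρ is
  calibrated per block by inverting the bivariate-normal orthant
  probability; allele frequencies are drawn per block (uniform in
  maf_range, default 0.1–0.5) so the calibration is exact and the
  empirical within-block dosage r matches the target. DZ twin pairs
  descend from four simulated parental haplotypes with whole-block
  transmission (preserves within-block LD; expected co-twin genotype
  correlation 1/2); MZ pairs are represented by a single emitted member.
- **Summary statistics.** Spike-and-slab standardized effects scaled to
  the requested SNP-h², converted to per-allele units, with Wald noise at
  the SE implied by the case/control counts. The true standardized
  effects are returned on request for oracle tests.
- **Phenotypes.** For each design cell, scores are NB draws with
  log-mean = a_cell + β_cell·G_std + person effect, truncated at 10,
  where G_std is the standardized true genetic value and
  β_cell = θ₀ + θ_age(age−4) + θ_reporter[teacher] + θ_trait[peer] +
  cohort offset. The default 29-cell design grid and cell means mirror
  the published descriptive moments of the two cohorts; a_cell is
  moment-matched so E[min(Y,10)] hits the cell mean exactly
  (Gauss–Hermite over the latent, NB survival identity, bracketing).
  The person-level log-scale latent (SD 0.5) induces the cross-measure
  correlation real SDQ subscales show; without it all measures are
  independent, M_eff = M and the composite V is diagonal. The NB size
  parameter defaults to 3, a compromise across the published cell SDs.
  Default θ = (0, 0.0025, 0.044, 0.03) — the ADHD-like profile.

What the generator does *not* emulate: participation/ascertainment bias,
assortative mating and dynastic effects, imputation uncertainty,
chip/batch artefacts beyond a random batch covariate, and real LD beyond
exchangeable blocks. Passing tests therefore show the estimators are
correct under the stated model, not that real-cohort estimates are
unconfounded.

One deliberate consequence of C+T scoring: the fitted β estimates
θ × corr(PRS, G), so recovered moderator coefficients are attenuated by
the score's imperfect correlation with the true genetic value (~0.85–0.9
at the default simulation scale). Recovery tests compare estimates
against generating values through their own standard errors, which
absorbs this attenuation at desk scale.

## Numerical choices

- NB GLM: Newton with tol 1e-10, BFGS fallback; non-convergence flagged.
- NB GLMM: L-BFGS-B on (β, log α, log σ); log σ floored at −10 where the
  likelihood switches to the exact fixed-effects form; SEs from a
  finite-difference observed information.
- Meta REML/ML: log-τ² bounded in [−30, 5]; multi-start; ftol 1e-13.
- Li–Ji: eigenvalues rounded at 1e-9 before the floor.
- Clumping ties: (p, position, ID); harmonization is idempotent.
- Intercept moment-matching: Brent bracketing, xtol 1e-8.

## Problem sizes

Simulation-heavy checks run at sizes chosen to keep the default suite
and the acceptance script in the minutes range on one CPU: LRT type-I
and Q-uniformity at 400 replicates (95% binomial/KS bands at that count),
coefficient CI coverage at 60 replicates (≥ 90% coverage bound),
covariance bias at 60 replicates, analytic-vs-MC power at 1,000
replicates of the semi-analytic simulator, pathway enrichment at 25
replicates, and the end-to-end profile recovery once per profile at
near-study-scale cohort sizes (5,000 unrelated; 2,400 DZ pairs + 800 MZ
singletons) with a 25-replicate effect-level recovery statistic across
all four disorder profiles.

## Known limitations

- The composite V uses phenotypic correlations as estimate correlations;
  the exact attenuation real effect estimates would show is not modelled
  (a sensitivity check rescales the correlations ×0.5/×1.5).
- The NB GLMM integrates one random intercept; crossed or nested
  multi-level structures are out of scope.
- The power model assumes independent post-clumping markers and a
  homogeneous effect mixture; LD-aware power is not attempted.
- Pathway scores reuse baseline clumping rather than re-clumping per set,
  diverging from tools that re-clump; this is what makes the screen's
  nesting logic exact.
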
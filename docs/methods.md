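# Methods

## The model

`twinvolve` implements the classical ACE decomposition for extended
twin-family data. For a trait measured on the members of family *f*, the
phenotype vector is modeled as multivariate normal,

    y_f ~ N( X_f * beta,  A * K_A + C * K_C + E * I ),

where A, C and E are the additive-genetic, shared-environment and unique-
environment variance components, `K_A` carries the additive relatedness
coefficients (1.0 between MZ co-twins, 0.5 between DZ twins and full
siblings, 1.0 on the diagonal) and `K_C` is 1.0 within a family. The mean
model `X_f * beta` always carries an intercept, sex (F = 0, M = 1) and age
(centered at the sample mean); total brain volume (TBV) can be added as a
global covariate for regional volumes. Standardized proportions are
`a2 = A/V`, `c2 = C/V`, `e2 = E/V` with `V = A + C + E`; they sum to one by
construction.

The bivariate model stacks two traits per person. Each 2x2 component
covariance matrix is parameterized by a lower-triangular Cholesky factor,
`Sigma_comp = L_comp L_comp'`, so positive semi-definiteness is structural.
Within a person the phenotypic covariance is `Sigma_A + Sigma_C + Sigma_E`;
between family members the A block scales with the additive coefficient and
the C block is shared, while E never crosses persons. Derived quantities:

* component correlation, e.g. `rG = A_xy / sqrt(A_x A_y)`;
* contribution to the phenotypic correlation,
  `pcorA = sqrt(a2_x) * rG * sqrt(a2_y)` (and likewise for C and E), whose
  three terms sum exactly to the model-implied phenotypic correlation. The
  quantity is deliberately not clipped to [0, 1].

When a component's variance in either trait falls below 1e-12 the
correlation is reported with `defined = False` instead of a number:
standardizing a near-zero covariance produces arbitrary +/-1 values that
carry no information.

## Estimation

Fitting is full-information maximum likelihood: every family contributes
the normal log-density of its observed phenotype entries (missing entries
are marginalized by dropping rows/columns of the mean and covariance), so
singletons, lone twins and partially phenotyped families all inform the
fit. Families are grouped by (size, relatedness pattern, missingness
pattern) and each likelihood evaluation factorizes one covariance per group,
scoring all of that group's families with vectorized solves — evaluation
cost is dominated by a handful of small Cholesky factorizations.

Variance components are optimized as path coefficients (`A = a^2`, ...),
keeping them non-negative without constrained optimization and making the
zero boundary exactly reachable. Phenotypes are standardized internally by
the OLS residual SD before optimization and the estimates mapped back, so
results are invariant to trait units (mm^3 volumes optimize as well as
z-scores); reported `-2 lnL` includes the Jacobian correction back to the
original scale. Optimization is BFGS with numerical gradients from several
deterministic-plus-seeded starting proportions (default 5); the best
deviance is kept, and the fit is flagged non-converged when the optimizer
fails, the gradient norm is large, or the two best starts disagree by more
than 1e-4 deviance units.

### Submodel tests

Dropping A or C puts the null on the boundary of the parameter space, so
the likelihood-ratio statistic is referred to a 50:50 mixture of a point
mass at zero and chi-square(1); dropping both (the familial AC test) uses
the 25:50:25 mixture over chi-square(0, 1, 2). Bivariate covariance-path
tests fix one cross-loading at zero; cross-loadings are interior
parameters, so plain chi-square(1) applies.

### Profile-likelihood intervals

A 95% bound for a quantity (a proportion, or a raw component) is the
extreme value at which the constrained minimum of `-2 lnL` (all other
parameters re-optimized; SLSQP with an equality constraint, started from
both the MLE and a constructed feasible point) exceeds the unconstrained
minimum by 3.841. The bound is located by bisection to 1e-3 on the quantity
scale; when the deviance stays under the threshold all the way to the edge
of the parameter space the bound is reported at the edge (0 or 1 for
proportions). Constrained-optimizer failures mark the interval untrusted
rather than silently returning a bound.

## The synthetic cohort generator

The generator emulates the structure of the study sample: 121 MZ pairs, 67
DZ pairs and 556 singletons (932 persons), 45% male, ages normal(28.8, 3.6)
truncated to 22-37 years, with an option to attach extra full siblings to
twin families. Phenotypes are built from latent standard-normal A/C/E
scores with family-block covariance `K_comp (x) R_comp`, where the
`R_comp` are cross-trait component correlation matrices (validated positive
semi-definite); sampling uses symmetric matrix square roots so singular
patterns (MZ pairs share their A score exactly) are handled without
jitter. Trait scales (means, SDs) and generating variance proportions are
read from the packaged calibration table (`fixtures/paper_tables.csv`);
printed proportions are renormalized to sum to exactly one. With covariate
slopes at their default of zero, `total_sd` is the marginal phenotypic SD,
so sample moments land on the published scale directly.

`cross_spec_for_phenotypic_r` converts a target phenotypic correlation into
equal component correlations `r0 = r_ph / sum_k sqrt(k2_x k2_y)` — the
least-committal choice when only the phenotypic correlation is reported.

What the generator does not emulate: assortative mating, dominance,
sex-limitation or age moderation of variance components, household
structure beyond one generation, measurement floor/ceiling effects, and
non-normal trait distributions. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated model
class, not robustness of the scientific conclusions to violations of twin-
model assumptions.

## Problem sizes and numerical choices

* Recovery experiments fit generating models on cohorts with the study's
  MZ/DZ/singleton mix scaled 8-fold (5,952 families; 16-fold for the
  working-memory model). Near a variance boundary (a2 = 0 or c2 = 0) the
  ML estimator of the boundary component is truncated upward and its
  complement biased downward by roughly 0.8 times the component's standard
  error; at the study's own size (~380 informative pairs) that bias
  reaches ~0.05-0.06, while at the scaled-up sizes it is within the
  recovery tolerance. The scale-up trades Monte-Carlo and truncation error
  for runtime; proportions are unaffected otherwise.
* Type-I error of the boundary A test is checked by simulating the null
  (a2 = 0) on small cohorts (60 MZ / 40 DZ / 60 singletons), 500
  replicates: the mixture reference distribution is an asymptotic result
  that holds at small n, so the cheap design is sufficient.
* Profile-CI coverage uses the study-sized cohort (932 persons) and the
  crystallized-cognition generating model, 50 replicates.
* Non-positive-definite covariance at an evaluated parameter point returns
  a large finite penalty (1e12) rather than raising, so optimizers can
  retreat from degenerate regions.
* Joint (bivariate) and marginal (univariate) MLEs of the same trait agree
  asymptotically but not identically — the bivariate likelihood is not
  variation-free in the marginal parameters — so cross-checks between the
  two use a finite-sample tolerance (~0.08 at 400 pairs).

## Phenotypic stage

Brain-behavior associations are ordinary least squares of behavior on ROI
volume plus covariates, with two effect sizes: the standardized slope and
the sign-consistent partial correlation `t / sqrt(t^2 + df)`. Family
clustering is deliberately ignored at this stage (a documented
simplification, consistent with treating the phenotypic screen as
descriptive); the genetic stages model it fully. FDR control is
Benjamini-Hochberg per named analysis family, with a global pooled variant
behind a flag. Correlation-matrix display order comes from a deterministic
average-linkage clustering on distance 1 - r with ties broken by input
order; ordering is cosmetic and carries no inferential weight.

## Known limitations

* No ADE, sex-limitation, dominance or assortative-mating models; the
  fitted class matches the generator's assumptions.
* The hypothesis-test ledger is configuration arithmetic; it does not force
  the pipeline to have executed exactly those tests.
* Bivariate models default to age and sex in the mean model; TBV enters
  only univariate ROI models unless configured otherwise.
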
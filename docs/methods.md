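# Methods

## Model representation

All model variables — observed variables, composites of interest,
excrescent variables, and latent variables — share a single ordering in
an all-endogenous (RAM-style) representation. A parameter table maps to
a coefficient matrix `A` (loadings and structural paths), a symmetric
matrix `Psi` (exogenous and residual variances/covariances) and a
selection matrix `G` picking the observed rows:

    Sigma(theta) = G (I - A)^-1 Psi (I - A)^-T G'.

Every matrix entry is *affine* in the free parameters: fixed entries are
constants, free entries carry one label, and constrained entries are
affine expressions over labels (e.g. the effects-coding loading
`1 - l_a - l_b`). Constraints are substituted out exactly rather than
imposed by a Lagrangian, so sum-to-one and sum-to-zero restrictions hold
to machine precision at every iterate, and the derivative of every
matrix entry with respect to every free parameter is a constant — the
engine exploits this for exact analytic gradients of the discrepancy and
of `Sigma` itself.

## Identification rules for composite blocks

For each block of `k` components the builder creates the composite of
interest plus `k - 1` excrescent variables and applies:

1. **Scale of the composite of interest.** Effects coding by default
   (loadings sum to 1); reference-variable (one loading fixed to 1) and
   variance-standardization (composite variance fixed to 1) methods are
   available for free-weight composites. Unit-weight composites use
   effects coding, which makes the composite the *sum* of its components
   (fixing the sum of loadings to `k` instead would give the average).
2. **Excrescent sparsity.** Each excrescent variable loads on exactly
   two components: one reference component and the block's shared
   component. No two excrescent variables touch the same pair, no
   component is a reference twice, and no component loads on more than
   two excrescent variables.
3. **Excrescent scale.** The reference loading is fixed to 1. The shared
   loading is free for unknown-weight composites and fixed to −1
   (sum-to-zero) for unit-weight composites.
4. **Orthogonality.** Covariances between the composite of interest and
   its own block's excrescent variables are fixed to 0 (explicit rows in
   the table). Within-block excrescent covariances are free — this is
   required for the block to reproduce its components' covariance
   submatrix exactly, and hence for the degrees-of-freedom arithmetic
   (11 / 8 / 3 on the illustrative model) to hold.
5. **Connectivity.** An unknown-weight composite must be connected to at
   least one other variable of the model; violating this is flagged at
   build time and is visible to the numeric local-identification
   diagnostic as a rank-deficient Jacobian.

The *relaxed* variant additionally frees the covariances between each
block's excrescent variables and every other block's composite and
excrescent variables (own-block orthogonality stays). On the two-block
illustrative model this adds 5 covariances, and the resulting model is
fit-equivalent to the one-step specification.

Component error variances are always emitted as explicit rows fixed
to 0, so composites are fully composed of their components.
Single-indicator latent variables get a unit loading and an indicator
error variance fixed to `(1 - reliability) * var(indicator)`, with the
indicator variance taken from the supplied sample moments in the divisor
convention they came in (matching the practice of computing these fixed
values from published standard deviations).

Defaults where the rules leave freedom: the shared component is the
block's first component and references are the remaining components in
declared order (both overridable); under effects coding the
substituted-out loading is the shared component's, so the recommended
zero starting values for free composite loadings leave the loading
matrix nonsingular at the start. χ², degrees of freedom, standardized
solutions and recovered weights are invariant to all of these choices
(tested to 1e-6).

## Baselines

* **One-step**: each composite is an endogenous variable regressed on
  its exogenous observed components with disturbance variance fixed
  to 0; one component coefficient is fixed to 1 (by default the last
  component of the block), and all component variances and covariances,
  within and across blocks, are free. A covariance between two one-step
  composites is structurally impossible and is rejected with an error;
  `one_step_spec()` strips such pairs when translating a conceptual
  model. Free weights start at the leading canonical-correlation
  direction between the block's components and the remaining observed
  variables (scaled to the fixed component) — free composite weights
  estimate exactly this kind of direction, and a data-driven start
  avoids wrong-sign local minima that plain unit starts can produce.
* **Two-step**: composite scores are computed first (`T S T'`, unit
  weights by default), then the structural model is fitted on the
  reduced moments. Its standardized structural estimates coincide with
  the unit-weight H–O ones; its fit statistics refer to a different
  covariance matrix and are not comparable.

## Estimation

The ML discrepancy `F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p` is
minimized with BFGS (scipy) using the analytic gradient
`dF = tr[Sigma^-1 (Sigma - S) Sigma^-1 dSigma]`; evaluations at
non-positive-definite `Sigma` return `+inf`, which the line search
treats as an infeasible step. Convergence requires a gradient sup-norm
of 1e-6 or better; on failure up to three seeded, jittered restarts are
attempted and the best solution is kept with `converged=False` rather
than raising. Starting values: 0 for free loadings, paths and
covariances (zero starts for composite loadings are a reliably good
choice in this parameterization); sample variances for observed-variable
variance parameters; block-component variance means for composite and
excrescent variances; half the indicator variance for latent
disturbances.

Sample moments carry a divisor tag. An unbiased (divisor n−1) input is
rescaled by `(n-1)/n` before fitting so that the test statistic
`chi2 = n * F` follows the divisor-n convention throughout; moments
computed from raw data default to divisor n.

## Standard errors and derived quantities

The parameter covariance is the inverse expected information at the
optimum scaled by the χ²-scaling sample size, `acov = I^-1 / n` with
`I_jk = 1/2 tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k)`, computed with the
analytic `dSigma`. Derived quantities — weights (first row
of the inverted block loading matrix), standardized weights
`w_i * sd(x_i)/sd(c)` and the standardized solution
`b_std = b * sd(source)/sd(target)` with model-implied standard
deviations — get delta-method standard errors with central-difference
gradients (relative step 1e-6). A singular information matrix yields
undefined (NaN) standard errors with a warning rather than an error.
Variance parameters are unbounded; inadmissible (Heywood) solutions are
allowed but warned about, matching common SEM software behavior.

Variance-standardized composites have a sign indeterminacy (`c` vs
`-c`); recovered weights and the standardized solution adopt the
orientation in which the composite's loadings sum to a positive value,
which makes the solution invariant across scale-fixing methods. The
standardized solution reports structural paths and covariances among
constructs; covariances involving excrescent variables are
parameterization-dependent nuisance quantities and are excluded unless
requested.

## Fit assessment

`chi2 = n * F` with `df = p(p+1)/2 - q` (no mean structure). The
baseline for the incremental indices is the independence model (all
observed variables uncorrelated, free variances), which has the closed
form `F_b = sum(ln s_ii) - ln|S|` and `df_b = p(p-1)/2`. RMSEA uses
`sqrt(max((chi2 - df)/(df*n), 0))`; SRMR averages squared residuals
standardized by sample standard deviations over all `p(p+1)/2` unique
elements including the diagonal; CFI and TLI use their conventional
definitions. Information criteria come from the normal log-likelihood:
AIC `= -2logL + 2q`, BIC `= -2logL + q ln n`, SABIC
`= -2logL + q ln((n+2)/24)`. For a saturated model (`df = 0`,
`chi2 = 0`) RMSEA is 0 and TLI is 1; a `df = 0` model with positive
χ² would report them as undefined.

χ² difference tests verify nesting structurally before comparing: every
parameter cell of the restricted table must be free in the full table or
determined identically in both (cells absent from a table count as fixed
zeros). A negative difference beyond numerical tolerance triggers a
convergence warning instead of being silently clipped.

## Synthetic population and what it does (not) show

The built-in population emulates the structure of the illustrative
forest-colonization model: blocks Soil {text, mois, pH} and Land
{age, dist}, single-indicator latents Comp (cover) and Colo (colf) with
reliability exactly 0.9 in the population, a saturated structural model
and a Soil–Land covariance. True values are documented constants
(`FIXTURE_TRUE_VALUES`), chosen so that (i) all implied variances are
positive, (ii) the soil weights are unequal — making unit- and
free-weight specifications distinguishable and the unit fit a genuine
misspecification — and (iii) all composite weights are positive, as in
the illustrative example, so the effects-coding and fixed-component sign
conventions orient the composites identically and the
specification-equivalence theorems are observable without sign
alignment. Indicator error variances are derived from the latent
variances (`var(latent)/9`), which makes the reliability-0.9 fixing
self-consistent when the model is fitted to its own population
covariance.

Sampling is exact multivariate normal (Cholesky), matching the ML
assumption. Passing tests therefore demonstrate correctness of the
estimator and the specification algebra under the model's own
assumptions; they say nothing about robustness to non-normality,
ordinal indicators, missing data or structural misspecification beyond
the variants studied.

Problem sizes used by the validation suite: the recovery study runs 200
replicates at n = 10 000 (bias of standardized paths < 0.02) and 500
replicates at n = 1 000 (95% CI coverage within [0.92, 0.98]); the χ²
calibration uses 500 replicates at n = 180; bootstrap checks of the
delta-method standard errors use 500 replicates at n = 500 (raw SD) and
n = 180 (robust spread — at n = 180 the weight sampling distribution is
heavy-tailed, as expected for elements of an inverted matrix, so the
asymptotic SE tracks the interquartile-based spread rather than the
outlier-inflated SD).

## Numerical choices

* Local identification: finite-difference Jacobian of `vech(Sigma)`
  (relative step 1e-6) at the supplied point plus two small random
  perturbations; singular values below `1e-8 * max` count as zero; the
  labels loading on the null space are reported. The analytic `dSigma`
  is cross-checked against this numeric route in the tests.
* Loading-matrix inversion for weight recovery refuses matrices with
  determinant below 1e-12 (degenerate solution).
* Moment matrices are symmetrized after an asymmetry check at 1e-8;
  text serialization uses 10 significant digits and round-trips exactly.

## Known limitations

* No mean/intercept structures, no missing-data (raw-data) likelihood,
  no robust or weighted least squares estimators, no ordinal indicators.
* Components must be observed variables; multi-indicator latent
  variables are limited to the single-indicator-with-fixed-reliability
  case.
* Fixed weights other than unit weights (or averages via the effects
  constant) are not supported.
* Non-recursive (cyclic) structural models are rejected.
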
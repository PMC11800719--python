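# Methods

## Model

We observe a binary (or continuous) phenotype `y_i`, covariates `Z_i`
(intercept, age, ...), an environmental exposure `D_i`, and minor-allele
counts `G_i` for `p` candidate SNPs.  The mixed model is

    g(mu_i) = Z_i theta + D_i alpha + Gs_i beta + (D_i * Gs_i) gamma + b_i,
    b ~ N(0, tau_g K + tau_d K_D),

with canonical link `g` (logit for binomial, identity for gaussian) and
`Gs` the column-standardized genotype matrix,
`(g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))` with `p_j` the sample allele
frequency; missing genotypes are mean-imputed (zero after
standardization).  `K = Gs_kin Gs_kin' / p_kin` is the genetic
relationship matrix computed from a SNP panel disjoint from the
candidates (the PLINK `--make-rel` standardized cross-product).  For a
binary exposure `K_D[i,j] = K[i,j] 1{D_i = D_j}`; for a continuous
exposure `K_D[i,j] = K[i,j](1 - d(D_i, D_j))` with the range-normalized
absolute difference as the default metric `d` (any metric into [0,1] is
accepted).  A principal submatrix argument shows the binary-masked `K_D`
inherits positive definiteness from `K`; rank-deficient `K` is jittered
to `K + 1e-4 I` (applied only when the smallest eigenvalue is at or below
`1e-8`, and before `K_D` is formed).

The GxE kinship models the covariance contributed by many small
polygenic-by-exposure effects: genetically related individuals sharing an
exposure are more alike than kinship alone implies.  Omitting it pushes
that signal into the fixed GEI coefficients and inflates their false
positive rate; the two-random-effect comparison in the acceptance suite
reproduces this at reduced scale.

## Two-step estimation

Joint optimization of variance components with the penalized fixed
effects would cost O(n^3) per iteration, so the variance components are
estimated once under the null of no genetic fixed effect
(`beta = gamma = 0`):

* PQL inner loop — iterated GLS on the working model `z = eta +
  (y - mu) g'(mu)`, `V = W^{-1} + tau_g K + tau_d K_D`, with working
  weights `w_i = a_i / (phi nu(mu_i) g'(mu_i)^2)`; a step-halving
  safeguard keeps the penalized quasi-likelihood non-decreasing.
* AI-REML outer step — Newton updates of `(tau_g, tau_d[, phi])` using
  the average-information matrix `AI_kl = z'P V_k P V_l P z / 2` and
  scores `(z'P V_k P z - tr(P V_k)) / 2`, with
  `P = V^{-1} - V^{-1}X(X'V^{-1}X)^{-1}X'V^{-1}`, `X = [Z, D]`.
  Components are truncated at zero; a component sitting at zero with a
  negative score is frozen.  For gaussian responses the dispersion enters
  as a third component with kernel `diag(1/a)`; for binomial data `phi`
  is fixed at 1 (standard PQL for binary traits).

Initialization sets each `tau` to 0.1 times the working-residual variance
from the fixed-effects GLM.  Convergence requires relative parameter
change below 1e-4 and the REML scores small; because the scores scale
with the sample size, "small" is assessed relative to the magnitude of
the REML log-likelihood (tolerance 1e-3) rather than on an absolute
scale.  Maximum 50 outer iterations, with the best iterate returned and
flagged when not converged.

Covariates are used on their original scale.  Known PQL caveat: for
binary traits the working-model linearization *under-estimates* large
individual-level variance components (a bias documented since the early
PQL literature).  The bias shrinks as random effects are shared across
observations, so the recovery oracle in the acceptance suite uses
cluster-block kinship (20 blocks of 50 exchangeable members) where the
components are identifiable; with individual-level structure the same
code is unbiased for gaussian responses but attenuates binary-trait
estimates by 30% or more.  This attenuation affects the *scale* of
`(tau_g, tau_d)` in the downstream ridge, not the hierarchy or selection
machinery.

## Penalized path

Given `(tau_g, tau_d)`, one eigendecomposition
`U diag(Lambda) U' = tau_g K + tau_d K_D` (computed once, never inside
the path loop) rotates the random effect to `delta = U'b` with a diagonal
ridge `delta' Lambda^{-1} delta / 2`.  The objective adds the composite
penalty `(1-rho) lambda ||(beta_j, gamma_j)||_2 + rho lambda |gamma_j|`
per SNP.  Its proximal operator is closed-form — soft-threshold the GEI
coordinate at `t rho lambda`, then group-shrink the pair at
`t (1-rho) lambda` — and can only zero `beta_j` together with `gamma_j`,
which is what enforces strong hierarchy at every iterate, for every
`(lambda, rho)`.

Each path point runs a proximal Newton loop:

1. freeze weights `W` and working response `z` at the current state (the
   weights vary slowly with the conditional mean);
2. update `delta` by the generalized ridge WLS solve
   `(U'WU + Lambda^{-1}) delta = U'W r`;
3. block coordinate descent on the frozen quadratic: the unpenalized
   block `(theta, alpha)` by exact WLS; each group `(beta_j, gamma_j)` by
   solving its 2x2 quadratic subproblem exactly, iterating the
   closed-form prox on majorized Newton steps with step size
   `1 / lambda_max(H_j)` (all-scalar, so the per-group solve is exact at
   negligible cost); cycles continue until the largest coefficient change
   falls below 1e-7;
4. a full vectorized subgradient sweep over inactive groups admits
   violators into the active set (glmnet-style active-set strategy);
5. if the true objective increased (the quadratic model overstepped),
   the step is halved toward the previous iterate.

Outer convergence: relative objective change below 1e-6, caps of 100
inner cycles and 50 outer iterations per path point.  At a fixed point of
the frozen-weight iteration the quadratic-model gradients coincide with
the exact quasi-likelihood gradients, so converged points satisfy the
exact KKT conditions (certified in the acceptance suite at 1e-4).

`lambda_max(rho)` is the smallest `lambda` for which every group passes
the zero-solution subgradient test
`||(grad_beta_j, soft(grad_gamma_j, rho lambda))|| <= (1-rho) lambda`
at the weights-converged null-covariate fit — closed form at `rho = 0`,
bisection (returning the feasible upper bracket) otherwise.  The default
grid takes 50 log10-spaced `lambda` values down to `0.01 lambda_max`
(the largest `lambda_max` over the 10-value `rho` grid on [0, 0.9], so
one `lambda` grid is shared by all sweeps and cross-validation surfaces
align) — 500 models in total.  Warm starts run across `lambda` within a
`rho` sweep; each sweep restarts from the null solution.  Interaction
columns are `D * Gs` (genotype standardization reused; the exposure
indicator is not rescaled).  Ties at the group threshold resolve to zero.

For large sweeps (thousands of SNPs times hundreds of active groups) the
inner tolerance can be relaxed to 1e-6; support sets are insensitive to
the tail of the coordinate iteration, and the reduced-scale experiment in
the acceptance suite uses this setting.

## Cross-validation and prediction

Folds are stratified by case status and seeded.  Variance components and
the spectral basis are estimated once on the full data and reused in all
folds (consistent with the two-step design and avoiding O(n^3) per
fold); each fold refits the path on its training rows, with the training
rows of `U` carrying the random effect, and scores the held-out rows by
binomial deviance (default) or AUC.  The selected pair minimizes the mean
validation loss; ties prefer the larger `lambda`, then the smaller
`rho`; the final model is refit on all samples by warm-starting down to
the selected `lambda`.  A one-standard-error variant is not implemented.

External subjects are scored with training-MAF-standardized genotypes;
their random effect is either zero or the conditional Gaussian mean
`b_new = Sigma_cross Sigma_train^{-1} b_tilde` with
`Sigma = tau_g K + tau_d K_D` blocks, both modes exposed because the
transfer rule is a modeling choice.

## Synthetic cohorts

The generator stands in for a harmonized whole-genome reference panel of
4097 individuals across 7 continental populations.  Genotypes follow the
Balding–Nichols model: ancestral frequency `q_j ~ U(0.05, 0.5)`,
population frequencies `Beta(q(1-F)/F, (1-q)(1-F)/F)` with drift
`F = 0.1` (typical of continental F_ST), genotypes `Binomial(2, freq)`,
population sizes at the reference shares (24/13/19/20/19/4/1%).  Columns
monomorphic or below MAF 0.01 in the realized sample are redrawn.  The
kinship panel (default 5000 SNPs at desk scale, standing in for the
50000 used at full scale) is drawn disjointly from the `p` candidates.

Causal architecture: `|S| = 100` main effects
`beta_j ~ N(0, h2_S sigma2 / |S|)` and `|S'| = 50` GEI effects
`gamma_j ~ N(0, h2_S' sigma2 / |S'|)`; hierarchical scenarios draw
`S'` inside `S` (100 causal SNPs), non-hierarchical scenarios draw them
disjointly (150).  The random effect is one draw
`eps ~ N(0, h2_g sigma2 K + h2_d sigma2 K_D)`.  Phenotypes:

    logit(pi_i) = logit(pi0_k) - log(1.3) Sex_i + log(1.05) Age_i / 10
                  + sum_S beta_j Gs_ij + sum_S' gamma_j Sex_i Gs_ij + eps_i

with per-population baseline prevalence `pi0_k ~ U(0.1, 0.9)`,
`Age ~ N(50, 10)` (the age distribution's parameters are a package
choice), and sex as the exposure, `Bernoulli(0.5)` independent of
population by default; an optional population-tilted exposure mode
induces gene–environment dependence.  Study conditions:
`(h2_S, h2_S') = (0.2, 0.1)` with `(h2_g, h2_d, sigma2) = (0.2, 0.1, 9)`
(low polygenic) or `(0.4, 0.2, 35)` (high polygenic), so each causal main
effect contributes about 0.2% of logit-scale variance.

What the generator does *not* emulate: linkage disequilibrium, admixed
ancestry, and family relatedness beyond population blocks.  Passing tests
therefore demonstrate correctness of the machinery and the qualitative
confounding phenomenon, not calibrated performance on real LD structure.
Note one measurable consequence of structure: standardized columns use
the total-sample allele frequency, so their realized variance exceeds 1
by roughly the between-population frequency-variance fraction (~8% at
`F = 0.1`, the Wahlund effect); the empirical per-SNP variance share is
accordingly slightly above the nominal `h2_S/|S|`.

## Problem sizes and numerical choices

The acceptance suite runs at desk scale: the hierarchy sweep uses
`n = 500, p = 2000` over the full 500-model grid; variance-component
recovery uses `n = 1000` with 50 replicates; the two-random-effect
comparison uses `n = 800, p = 5000` with 20 replicates, a single
mid-grid `rho`, a 20-value `lambda` grid truncated once the GEI model
size reaches the causal count, and compares false positive rates at
matched GEI model size (the cross-validated full-scale design selects
model sizes too large to be reproducible at this `n`).  The acceptance
script measures the simulator's variance budget on 50 replicates at the
full `n = 4097, p = 10000` configuration.

Degenerate inputs: monomorphic SNPs and out-of-domain genotype entries
are rejected with the offending SNP named; fitted probabilities reaching
the (0,1) boundary raise (separation); collinear fixed-effect columns are
rejected; an all-zero gradient yields `lambda_max = 0` with a warning.
The hot coordinate-descent loop is JIT-compiled (numba); everything else
is vectorized numpy/scipy linear algebra.
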
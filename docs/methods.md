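# Methods

## Model

For individual *i*, trait *k* and visit time *t* (years from the
individual's baseline), the phenotype is modelled as

    y_ikt = mu_k + a_k t + c_k s_i + l_k s_i t
            + sum_tau alpha_ktau Cov_itau + sum_gamma beta_kgamma Cov_igamma
            + g_ik0 + g_ik1 t + e_ikt

where `s_i` is the variant dosage, `c_k` and `l_k` are the variant's
cross-sectional (CS, level) and longitudinal (LT, rate-of-change) effects
on trait k, `(g_ik0, g_ik1)` are per-individual random intercepts and
slopes, and `e_ikt` is the residual.  Stacking K traits trait-major, the
random effects have covariance `G` built from a 2K x 2K matrix `C`
(covariances of CS and LT components within and between traits) replicated
per individual, and the residuals have covariance `R = E (x) I_n` with `E`
the K x K same-visit residual covariance.  There is no genetic relationship
matrix; the random intercept/slope structure is the polygenic model.

Missing (individual, trait, time) slots are kept as all-zero rows of `y`,
`X`, `Z` and the SNP design on a common record grid (the union of each
individual's visit times).  Zero rows contribute nothing to any
cross-product; individuals missing one trait still inform it through the
cross-trait genetic covariance in `C`.

## Solver

Henderson's mixed-model equations are pre-multiplied by `diag(I, B)` with
`B = (Z'R^-1 Z + G^-1)^-1`, turning the large random-effects block into an
identity.  `Z'R^-1Z + G^-1` is a K x K grid of trait partitions, each of
which is block diagonal with one 2 x 2 atomic block per individual.
`recursive_partition_inverse` peels one partition row/column per round
with the four-block (Schur complement) identity; every Schur complement is
again partition-diagonal so only atomic blocks are inverted, each round's
result overwrites the growing lower-right inverse in place, and the
structural sparsity pattern of the input is preserved exactly.  Cost is
linear in individuals and roughly quadratic-to-cubic in traits, against
cubic in the full order (2NK) for dense inversion.

Each variant then borders the solved null system with its 2K equations
(CS and LT per trait).  `H22^-1 J2` is the stored null solution and
`H22^-1 H21` is obtained by re-solving the transformed system with a new
right-hand side, so no large inverse beyond `B` is ever formed.  Effects
and standard errors come from the dense 2K x 2K Schur matrix; p-values are
two-sided standard-normal tail areas of beta/SE, floored at the smallest
positive double.

Every per-variant quantity is linear in the dosage vector g (or g^2)
against per-individual tensors fixed by the null system, so a scan is a
small number of dosage-matrix products followed by batched 2K x 2K solves.

### Numerical form of the bordered solves

The textbook Woodbury expressions (`H - H B H` with `H = Z'R^-1Z`) cancel
catastrophically when `E` is nearly singular, because the operands carry
the scale of `R^-1` while the result carries the scale of `V^-1`.  The
engine therefore uses the algebraically identical product forms implied by
`B^-1 = H + G^-1`:

    H - H B H  =  G^-1 - G^-1 B G^-1,        I - H B  =  G^-1 B,

and computes `B x` for `R^-1`-scaled right-hand sides by per-individual
linear solves with `Z'R^-1Z + G^-1` (backward stable; the error scales
with the small result rather than with `||B||` times the large operand).
The recursive inverse is still used directly wherever the operands are on
the benign `G^-1` scale.  If the supplied `E` has condition number above
1e4 its spectrum is floored at 1e-4 of the largest eigenvalue (logged);
see "Variance components" for why this matters and why it is safe.

## Variance components

`C` and `E` are estimated on the null model (no SNP terms) by pairwise
bivariate AI-REML: restricted-likelihood score and average-information
matrix assembled from per-individual blocks, grouped by observation
pattern so that all contractions vectorise.  The optimiser works on
Cholesky factors of `C` and `E`, which keeps both matrices positive
semi-definite at every iterate and approaches boundary optima (vanishing
variances) smoothly; steps are damped Levenberg-Marquardt with step
halving, so the restricted likelihood never decreases.  Convergence is
declared when both the likelihood change and the relative parameter change
drop below the tolerance (default 1e-6), or when the likelihood has
plateaued under lightly damped steps while parameters drift along a flat
ridge.  Starting values are method-of-moments: the within-individual,
cross-visit covariance (free of residual variance) initialises the CS
block, baseline covariances give the residual block, and follow-up
variance inflation over the mean squared interval gives the LT variances.

The K-trait matrices are assembled from the K(K-1)/2 pairwise fits: each
trait's own blocks are averaged over its K-1 fits, cross-trait covariances
are unique to their pair.  Averaged variances with unique covariances can
leave `E` indefinite, because with two visits per individual the
CS-variance/residual split is only weakly identified (separating them
requires extrapolating cross-visit covariances from the 4-9 year interval
range back to zero): the pairwise fits agree on the well-identified
same-visit total `C_CS + E` but not on its split.  The repair therefore
floors `E`'s spectrum (relative floor 1e-4) and moves the amount removed
into the CS block of `C`, preserving the fitted same-visit covariance
exactly.  Flooring `E` alone would understate residual variance in the
floored direction by orders of magnitude and wreck test calibration; the
coherent shift only perturbs the model's cross-visit covariance by the
(small) repair magnitude.  The scan itself depends on `V = ZGZ' + R`, not
on the split, so this canonicalisation is statistically neutral.

Polygenic heritabilities are `var_CS / (var_CS + var_LT + var_res)` per
trait, and analogously for LT, from the null-model components.

The scenario runner re-estimates components in every replicate (the
faithful path) with a looser REML tolerance of 1e-3; the components are
far less precise than that stopping rule either way.  A fast path uses the
generating truth instead.

## Simulation

Defaults reproduce the published study conditions: 10,000 independent
variants with allele frequencies Beta(2, 10) + 0.01 and Hardy-Weinberg
dosages; three correlated traits; 100 causal variants with effects drawn
from MVN(mu, Sigma) where E(beta) = 10, E(delta) = 10/L,
var(beta) = [[10, 8, -7], [8, 12, -1], [-7, -1, 18]],
var(delta) = var(beta)/L, and a fixed CS-LT cross-covariance block; all
remaining variants carry infinitesimal background effects from
MVN(mu/1000, Sigma/1000); residual covariance equal to var(beta); two
visits per individual, the second Uniform[4, 9] years after baseline
(read as continuous; the distribution is not otherwise constrained); one
standard-normal time-independent covariate with fixed-effect coefficients
(alpha0, alpha1, alpha2) = (0, 1, 1), values that only shift location and
scale and do not affect power or type-I error under a correctly specified
model.

Two consequences of this construction are worth noting.  First, the
realized polygenic variance (~3300 per trait at baseline) dwarfs the
residual (~10-18), i.e. baseline heritability is close to 1, and the
residual covariance is close to unidentifiable (its information-based
standard error at n = 3000 is ~40); the engine's coherence-preserving
repairs above exist exactly for this regime.  Second, "type I error"
counts the 9,900 background variants, whose effects are tiny but real, so
mild inflation above the nominal Bonferroni level is expected and observed,
more for LT than CS.

The minor-allele-count filter requires at least `min_count = 3`
individuals in every carrier-genotype x time-interval category (dosage
classes 1 and 2 crossed with follow-up intervals binned to the nearest
year).  This reading reproduces the published realized Bonferroni
thresholds (about 68% of variants tested at n = 3000); a literal
"frequency of the dosage x time vector > 3/N" rule is also implemented
(`rule="dosage_time"` or `"both"`) but passes essentially all variants at
these sample sizes.

Missingness is injected either per record (random rows of one trait) or
per individual (both visits of one trait removed); individuals left with
no usable baseline are dropped and counted.

What the generator does not emulate: linkage disequilibrium (variants are
independent), population structure or relatedness, more than two visits,
time-dependent covariates, non-Gaussian phenotypes.  Passing tests
therefore validate the solver and its calibration under the stated
conditions, not robustness to confounding in real cohorts.

## Comparators

The single-trait scan is the K = 1 reduction of the same engine with the
trait's own blocks of `C` and `E`; under individual-level missingness it
loses those individuals entirely, which is the mechanism behind the joint
model's smaller standard errors and higher power for the affected trait.
The rate-of-change GWAS collapses two visits to `(y2 - y1)/dt` and runs
OLS per variant with the scaled baseline value as a covariate and no time
term, with normal-theory Wald p-values.

## Evaluation

Per replicate: the Bonferroni threshold is 0.05 divided by the number of
variants passing the filter; power is the fraction of causal (tested)
variants below threshold, averaged over traits; type-I error is the same
fraction among non-causal tested variants, per effect type.  Scenario
aggregates are plain means with Monte-Carlo standard errors; replicate r
of a scenario uses seed `master_seed + r`.

Problem sizes used in the shipped test suite: 20 replicates per arm for
the effect-ratio family (L in {1, 5, 20, 50, 100}, n = 3000) and for the
n in {1000, 2000} arms of the sample-size family, 6 replicates at
n = 10,000, and 10 replicates per missingness arm; the n = 3000 arm is
shared between families.  Null-uniformity uses one draw of 5,000 variants
with zero causal variants; parameter recovery uses 50 bivariate replicates
at n = 2000.

## Known limitations

- Wald z-tests only; no score or likelihood-ratio alternatives, no
  saddlepoint correction for case-control imbalance (quantitative traits
  only).
- The pairwise assembly is a heuristic; a joint K-trait REML would be
  coherent by construction but costs K^2 more per iteration.
- With exactly two visits per individual the residual/CS split is weakly
  identified (see above); reported heritabilities inherit that noise even
  though scans do not.
- Genomic inflation is reported through realized type-I error, never
  corrected.
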
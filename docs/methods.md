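# Methods

## Overview

`knockblock` implements a two-stage workflow for testing conditional
independence hypotheses in genome-wide association studies with group-level
false discovery rate (FDR) control, using only summary statistics at
inference time.

**Stage 1 (LD processing, `solveblock`).** From individual-level genotypes
the package estimates a block-diagonal correlation (LD) matrix, partitions
each block into groups of tightly correlated variants, and solves a
maximum-entropy optimization that yields the parameters of the joint
Gaussian law of original and knockoff Z-scores. The output is a compact
HDF5 bundle `(Sigma_i, S_i, D_i, groups, keys)` per block that contains no
individual-level data and can be shared.

**Stage 2 (inference, `ghostgwas`).** Given marginal GWAS Z-scores and a
bundle, the package samples `m` exchangeable knockoff copies of each
Z-score ("ghost" sampling — no genotypes needed), aggregates squared
Z-scores into per-group importance statistics, and applies the
multiple-knockoff kappa/tau filter at a target FDR.

The FDR guarantee is conditional on the modeling assumptions: variants in
different blocks are (approximately) independent, and the second-moment
(Gaussian) approximation of the genotype law is adequate for the
second-order statistics used downstream.

## Model and procedure

### Block-diagonal LD

For `p` variants the correlation matrix is approximated as
`Sigma = diag(Sigma_1, ..., Sigma_b)`. Block boundaries are found per
chromosome by an exact dynamic program over contiguous partitions that
minimizes the sum of squared cross-block correlations, counting only pairs
with `r^2 >= thr_r2` (default 0.01), declaring any partition that separates
a pair with `r^2 > max_r2` (default 0.3) infeasible, and constraining block
sizes to `[min_size, max_size]` (defaults 500 / 1000; a terminal remainder
block may be smaller, and a chromosome with no feasible partition becomes a
single block with a warning). Ties in cost are broken toward fewer blocks,
then toward lexicographically earliest boundaries, so the splitter is
deterministic. The DP cost uses an `O(p^2)` table of pairwise `r^2`, which
bounds practical block-splitting inputs to `p` of order 10^4 per
chromosome.

This splitter is a from-scratch implementation guided by the stated
parameter semantics; it guarantees the optimum of the documented objective
(verified against exhaustive enumeration in the tests) rather than
reproducing any external tool's boundaries.

### Correlation estimation

Within block `i` with column-standardized genotypes `X_i` and optional
covariates `C` (intercept added if absent):

    M_c   = I - C (C'C)^-1 C'            (residual-maker)
    X_adj = M_c X_i
    Sigma_i = X_adj' X_adj / n

Standardization uses the divisor-`n` standard deviation so the raw
`X'X / n` has an exactly unit diagonal. Covariates are residualized from
the *standardized* matrix, and the divisor stays `n` (not `n - q`). For
numerical stability the eigenvalues of `Sigma_i` are floored at `1e-5`
and the matrix is then rescaled symmetrically (`D^-1/2 Sigma D^-1/2`) to
restore an exactly unit diagonal; the rescale can pull the smallest
eigenvalue slightly below the floor, so validation checks `>= 1e-6`.
Only variants passing QC (MAF >= 0.01, Hardy-Weinberg chi-square
p >= 1e-6, biallelic hard calls) contribute. The Hardy-Weinberg test is
the Pearson 1-df chi-square of observed genotype counts against
`n (p^2, 2pq, q^2)`; an exact test is not used, which is a good
approximation at MAF >= 0.01.

### Grouping and group keys

Groups come from average-linkage hierarchical clustering on the distance
`1 - |r|`, cut inclusively at height `1 - cutoff` (default cutoff 0.5), so
merged clusters have average absolute correlation at least the cutoff.
Absolute correlation is used because negative LD is as informative as
positive for grouping.

Within each group, *group-key* variables are chosen by greedy forward
selection: repeatedly add the member that maximizes the average squared
multiple correlation `R^2(j | selected)` of the still-unselected members,
stopping once that average reaches `c` (default 0.5). The stopping rule
uses the *average* (not worst-case) explained variance; the greedy search
is validated against a brute-force smallest-subset oracle on small groups,
where it attains the minimum on well-behaved correlation structures but
may select extra keys on adversarial ones (it never under-selects).

### Maximum-entropy knockoff parameters

With `A = ((m+1)/m) Sigma_i(R, R)` on the key set R, the decorrelation
matrix `S_i` solves

    max_S  log det(A - S) + m log det(S)
    s.t.   S >= 0,  A - S >= 0,

with `S` constrained block-diagonal with respect to the group structure
restricted to keys. The block-diagonal constraint is required for group
exchangeability of the knockoff construction. `m = 5` knockoff copies per
feature is the default.

The solver is cyclic coordinate ascent. Diagonal steps have the closed
form `delta = (m u - v) / ((m+1) u v)` with `u = [S^-1]_jj`,
`v = [(A-S)^-1]_jj`, clipped to the open interval keeping both barriers
finite. Off-diagonal within-group steps maximize
`m log q1(delta) + log q2(delta)` — where `q1, q2` are the exact rank-two
determinant factors — by bounded scalar search inside the positivity
interval of both quadratics. Inverses are maintained by Sherman-Morrison /
Woodbury updates (BLAS symmetric rank-1 kernels on the lower triangle) and
re-factorized every 10 sweeps for numerical hygiene; the objective is
tracked incrementally through the same determinant factors, so every sweep
is `O(r^2)` per coordinate. Iteration stops when the relative objective
change per sweep falls below `tol` (default 1e-6) or after `max_iter`
sweeps (default 1000, with a warning). The trace is monotone
non-decreasing by construction; any terminal feasibility slack beyond the
`1e-8` eigenvalue tolerance is repaired by backtracking toward the
initializer (logged).

Initialization is `S^0 = 0.9 * min(1, ((m+1)/m) * lambda_min(Sigma_RR)) * I`,
which is always a strictly interior point of both log-det barriers. (A
start of the form `min(1, 2 lambda_min) * I` is *not* feasible whenever
`lambda_min <= 0.75`, since `1.8 lambda_min > 1.2 lambda_min`; the
initializer above avoids that failure mode.)

From the key-level optimum, the full sampling matrix in (R, C) order is

    D = [[S,    S A ],        A    = Sigma_RR^-1 Sigma_RC,
         [A'S,  D_22]],       D_22 = Sigma_CC - Sigma_CR Sigma_RR^-1 Sigma_RC
                                     + A' S A,

permuted back to variant order and verified to satisfy `D >= 0` and
`((m+1)/m) Sigma - D >= 0` within `1e-8` in eigenvalue.

### Ghost-knockoff sampling

Given marginal Z-scores `z` for a block, the knockoff copies are

    z_k = (I - D Sigma^-1) z + e_k,       k = 1..m,

where the noise vector across copies has the Kronecker-structured
covariance `I_m (x) D + 1_m 1_m' (x) W`, `W = D - D Sigma^-1 D`. An
orthogonal rotation in copy space whose first direction is `1_m / sqrt(m)`
block-diagonalizes this joint covariance into one `D + mW` factor plus
`m - 1` independent `D` factors, so the exact joint draw needs only
`p x p` eigenfactorizations. `W` alone may be slightly indefinite
(feasibility only guarantees `D >= 0` and `D + mW >= 0`); eigenvalues of
the two factor matrices are clipped at zero within a relative tolerance of
`1e-6` and anything beyond that raises, flagging a corrupted bundle.

Marginal Z-scores are computed as the score statistic
`z_j = X_j' y_tilde / sqrt(n)` with `y_tilde` the covariate-residualized,
standardized phenotype. The `sqrt(n)` normalizer is the convention that
makes null scores N(0, 1), which the knockoff machinery requires.

### Group statistics and the filter

Default group importance is the within-group sum of squared Z-scores,
`T_g,0 = sum_{j in g} z_j^2` and `T_g,k` likewise for each knockoff copy;
the importance transform is pluggable (a penalized pseudo-regression on
summary statistics could be substituted, at the cost of extra modeling
choices — it is not the default because the default must be fully
specified and dependency-free). The multiple-knockoff filter computes per
group `kappa_g` (the argmax column, ties broken toward a knockoff,
conservatively) and `tau_g` (max minus the median of the remaining `m`
values), then selects `{kappa = 0, tau >= t_hat}` at the data-dependent
threshold

    t_hat = min{ t > 0 : (1/m + (1/m) #{kappa != 0, tau >= t})
                          / max(1, #{kappa = 0, tau >= t}) <= q }.

The `1/m` offset is the "+1" correction of the knockoff filter; the median
of non-maximal copies is a standard multiple-knockoff choice.

For benchmarking, a marginal comparator selects variants with two-sided
normal p-value strictly below `5e-8`, and discoveries are merged into
independent loci by a greedy left-to-right pass with a 1 Mb window.

## Synthetic data

The generator emulates block-LD diploid genotypes under Hardy-Weinberg
equilibrium: per block, a latent Gaussian with equicorrelated (`rho`) or
AR(1) structure is thresholded at each variant's allele-frequency quantile
independently for two haplotypes, and the haplotypes are summed. Variant
positions sit on a 5 kb grid so megabase-scale locus merging is
meaningful. Default study conditions: n = 1000 samples, three
equicorrelated blocks of 200 variants with latent `rho = 0.4`, allele
frequencies uniform on [0.05, 0.5], `k = 10` causal variants with effects
`N(0, 0.5)` (`effect_sd = sqrt(0.5)`, reading the 0.5 as a variance),
noise variance 3, `m = 5`, target FDR 0.10, 200 repetitions. Phenotypes
are standardized after simulation. Per-repetition random streams are
spawned from the master seed, so repetitions are independent and
individually reproducible.

With standardized independent columns these defaults give an expected
heritability around `k * effect_sd^2 / (k * effect_sd^2 + 3) ~ 0.625`;
heritability is a derived quantity of the configuration, not a separately
asserted target.

What the generator does *not* emulate: linkage decay along the chromosome
(within-block correlation is exchangeable, not distance-decaying),
relatedness and cryptic population structure, admixture, genotyping error,
and realistic allele-frequency spectra. Passing FDR-control tests on this
generator therefore demonstrates the statistical machinery under the
block-independence and HWE assumptions; it does not by itself certify
performance on real cohort data, where block misspecification and
relatedness are the main risks.

The end-to-end experiment uses the generating block boundaries by default
(`use_true_blocks=True`); block boundaries are a pre-processing input of
the LD stage, and the splitter is exercised by its own oracle tests.
Setting `use_true_blocks=False` runs the splitter inside the loop.
Causal variants are drawn on the post-QC standardized matrix, so a causal
variant is never silently removed by QC. A selected group counts as a
true discovery iff it contains at least one causal variant (the standard
group-knockoff convention).

## Numerical choices and edge cases

- PSD tolerances: `1e-8` on eigenvalues for optimizer/assembly
  feasibility; `1e-6` relative for the sampling factorizations; Sigma
  validation on bundle load requires symmetry within `1e-10`, unit
  diagonal within `1e-10`, min eigenvalue `>= 1e-6`.
- Clustering ties: the dendrogram cut is inclusive at exactly
  `1 - cutoff`; linkage ties resolve deterministically through the
  implementation's ordering.
- `kappa` ties (exact equality of the max) resolve toward a knockoff
  column, which can only lose power, never inflate FDR.
- Z-score alignment requires an exact (chrom, pos, ref, alt) match; a
  ref/alt swap is accepted with the Z sign negated and logged; any other
  mismatch drops the variant (with a count report) and the block's
  `Sigma`/`D` are restricted to the matched subset — principal submatrices
  preserve both PSD constraints.
- Monte-Carlo moment checks compare each empirical moment to its target
  within 3 standard errors; across hundreds of simultaneous entries a
  ~0.3% exceedance rate is expected by chance, so the acceptance check
  bounds the exceedance fraction at 1% rather than requiring literally
  every entry inside 3 SE.
- Half-calls and `./.` in VCF GT are treated as missing; allele indices
  above 1 raise with instructions to split multi-allelic records.
- Missing dosages are mean-imputed before standardization; columns that
  are entirely missing or constant raise, naming the variant.

## Problem sizes

The test suite and the reproduction script run the full pipeline at
n = 1000, p = 600 over 200 repetitions, with optimizer sweeps of order
tens per block; oracle comparisons (exhaustive partition enumeration,
grid searches) run at p <= 30 and |R| <= 3 where enumeration is exact and
cheap. Blocks beyond p of order 10^4 are outside the intended envelope of
the dense solver.

## Known limitations

- The splitter's objective is this package's documented interpretation of
  squared-cross-correlation minimization under the stated knobs; other
  tools may use different objectives and return different (also valid)
  boundaries.
- Greedy key selection may exceed the minimal key set on adversarial
  correlation structures.
- No BGEN/PGEN input, no dosage (non-hard-call) genotypes, no
  mixed-model Z-scores (use external LMM software and feed the resulting
  Z-scores in), no meta-analysis, no effect-size estimation.
- The HDF5 schema is this package's own (versioned); byte-compatibility
  with other tools' LD bundles is not claimed.
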
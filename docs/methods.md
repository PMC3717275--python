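# Methods

## Model and test statistics

Let X be the n × p matrix of a gene set's expression values (samples in
rows, centered per gene) and Y a continuous phenotype with centered version
Y_c. All four tests are *self-contained*: significance is assessed by
permuting the phenotype across samples, which leaves the gene–gene
correlation structure intact, and the null hypothesis is that no linear
combination of the set's genes is associated with Y.

**Shrinkage covariance.** The sample covariance Ω̂ (unbiased, n−1
denominator) is singular whenever p ≥ n. We therefore use a
correlation-shrinkage estimate: sample variances are kept exactly, and each
off-diagonal entry becomes ρ̂_{hh'} · min(1, max(0, 1−λ̂*)) · √(ω̂_hh ω̂_h'h').
The intensity

λ̂* = Σ_{h≠h'} V̂ar(ρ̂_{hh'}) / Σ_{h≠h'} ρ̂²_{hh'},  clamped to [0, 1],

uses the empirical variance of the standardized cross-product terms
w_{hh'l} = z_hl z_h'l (z the (n−1)-standardized data):
V̂ar(ρ̂_{hh'}) = n/(n−1)³ · Σ_l (w_{hh'l} − w̄_{hh'})². Degenerate corner: if
every off-diagonal sample correlation is exactly zero (including p = 1) the
denominator vanishes and we return λ̂* = 1; the covariance is already
diagonal so the choice has no effect on Ω̂*. Zero-variance genes are an error
at this layer (correlations undefined); the screening layer removes them,
with a warning, before calling.

**LCT.** Maximising the squared sample correlation of Y with Z(β) = Σβ_hX_h
gives ρ²(β*) ∝ Ĉov(Y,X)ᵀ Ω̂*⁻¹ Ĉov(Y,X). With the eigendecomposition
Ω̂* = UDUᵀ and the whitened matrix V = X_c U D^{−1/2}, this equals
Σ_j Ĉov(Y, V_j)² up to a positive constant that cancels under permutation.
The eigendecomposition depends only on X, so it is computed once per dataset
and reused for every permutation; a permutation pass is then a single matrix
product of the permuted phenotype rows with V.

**LCT₂.** The squared L₂ norm of the regularised regression function
f̂ = X_c ((n−1)Ω̂*)⁻¹ X_cᵀ Y_c. Replacing the centered Gram matrix
X_cᵀX_c = (n−1)Ω̂ by (n−1)Ω̂* is the unique substitution consistent with the
LCT construction: it reduces to the OLS fitted values when λ̂* = 0 and X_c
has full column rank, and remains defined when p > n. The inverse is applied
through the stored eigendecomposition (a pseudo-inverse over retained
components).

**SAM-GS (continuous).** Σ_h (α̂₁ₕ/SE(α̂₁ₕ))², the squared Wald statistics of
the slopes from the p simple regressions of Y on each gene. We regress Y on
the gene (not the reverse), matching the univariate working model
Y_i = α₀ + α₁Z_i + e_i. A gene exactly collinear with Y has zero residual
variance and an infinite Wald term; this raises an error naming the gene. A
constant phenotype returns 0 by convention so the degenerate permutation
case (all permuted statistics equal) yields p = 1.

**Global Test.** The score statistic of the random-effects formulation,
Q = Y_cᵀ X_c X_cᵀ Y_c / p. Any positive constant is permutation-invariant;
1/p keeps values comparable across set sizes. Significance is by
permutation, not the asymptotic reference distribution.

**Permutation engine.** p = (1 + #{b : T(Y_πb) ≥ T(Y)}) / (B + 1), with
permutations drawn uniformly (not forced distinct), ties counted toward the
numerator, and one seeded B × n index matrix shared by all statistics in a
comparison run (and by all sets in a screening run) so that method and set
comparisons are not confounded by permutation noise. The add-one convention
guarantees p > 0 and validity of the test.

## Numerical choices

- Eigenvalues below 1e-10 × (largest) are dropped from the whitening
  transform; D^{−1/2} must not amplify rounding noise. With λ̂* > 0 and
  positive variances all eigenvalues are positive in exact arithmetic.
- Tiny negative eigenvalues from `eigh` rounding are clipped to zero.
- Whitening identity transformᵀ Ω̂* transform = I is tested to 1e-8.
- Per-gene regressions treat residual sums of squares below 1e-12 relative
  as collinear (error) rather than returning astronomically large Wald terms.
- External files are genes × samples (microarray convention); orientation is
  converted exactly once at ingest, and all internal linear algebra is
  samples × genes.

## Simulation framework

Each replicate draws X with i.i.d. MVN(0, C) rows, where C is block
correlation with unit variances: a p1-gene compound-symmetry block
(pairwise ρ), a p2-gene AR(1) block (ρ^|i−j|), and an independent remainder.
C is Cholesky-factored once per scenario. The phenotype is Y ~ N(Xμ, I).
Under the null μ = 0; under the alternative exactly five of the first twenty
components of μ are drawn from N(ν, |ν|) and five of the next twenty from
N(−ν, |ν|) (|ν| read as a variance, matching the N(mean, variance) notation
used for the error term), the rest zero. μ is re-drawn for every replicate:
the random placement and magnitude of effects are part of the generative
model, so power is averaged over them rather than conditioned on one draw.

Mean 0 and unit variances for X are a modelling choice (only the correlation
structure is constitutive; the effect enters through Xμ). Per-replicate
generators derive from SeedSequence((scenario seed, stream, replicate)), so
experiments are reproducible and parallelisable, and distinct scenarios
should be given distinct seeds — reusing one seed across scenarios makes
their Monte-Carlo errors strongly dependent because the phenotype stream is
shape-independent in n.

Default experiment sizes follow the study design: 1000 replicates × 1000
permutations for type-I-error tables; trend and power checks in the test
suite use 300 replicates and 500–1000 permutations, which keeps the full
suite in the minutes range while leaving binomial standard errors (~0.013 at
a level of 0.05) small relative to the effects being asserted.

## Screening pipeline

Gene rows are standardized (mean 0, sd 1, n−1 denominator; zero-variance
genes dropped with a warning). Sets are intersected with the measured genes
first and then filtered on the analyzed size, inclusive 15–500 by default —
filtering on annotated size would retain sets whose measured content is far
smaller than nominal. Duplicate genes within a GMT line are dropped at parse
with a warning. All sets and methods share one permutation index matrix.
Storey q-values use the fixed-λ estimator π̂₀ = min(1, #{p > 0.5}/(0.5·m))
— deterministic and adequate for screening, unlike the bootstrap/smoother
variants — with q_(i) = min_{j≥i} π̂₀·m·p_(j)/j; forcing π̂₀ = 1 recovers
Benjamini–Hochberg, which the tests exploit as an oracle. q-values are
computed independently per method. When the phenotype is itself a gene's
expression row (the marker-gene design), that gene is left inside tested
sets by default; the CLI exposes `--drop-phenotype-gene` to remove it.

## What the synthetic data does and does not emulate

The generator reproduces the statistical skeleton of a small expression
study — short samples axis, wide gene axis, blockwise correlation, sparse
linear effects, Gaussian marginals. It does not emulate heavy-tailed or
skewed expression distributions, batch or array effects, missing values,
probe-level artefacts, or annotation noise in catalogs. Passing tests
therefore certify the inferential machinery (exactness of the permutation
tests, correctness of the statistics, ranking behaviour of the screen), not
robustness to real-data pathology; the strict parsers refuse incomplete
matrices rather than imputing them.

## Known limitations

- Only linear association is tested; covariate adjustment and GLM
  extensions (counts, survival) are out of scope.
- Permutation p-values have granularity 1/(B+1); screening at stringent FDR
  thresholds needs B well above the default 1000.
- The shrinkage target is the diagonal of sample variances with a single
  intensity; alternative targets are not implemented.
- A self-contained test can be driven by a few genes of a large set;
  core-subset reduction is not provided.
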
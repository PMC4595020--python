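# Methods

This note documents the models, the simulator, the parameter defaults, and
the numerical choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The marker-effects model and its solvers

All linear methods share the predictor

    y_j = μ + Σ_k x_jk β_k δ_k + e_j,

with `x_jk ∈ {0, 1, 2}` the minor-allele dosage of marker `k` in individual
`j`.  Methods differ in the prior/penalty on `β` and in whether the
inclusion indicators `δ_k` are free.

### rrBLUP, GBLUP and REML

With `δ_k = 1` and `β_k ~ N(0, σ²_β)`, writing `g = X_c β` (column-centered
dosages) gives the individual-level model `y = μ1 + g + e`,
`g ~ N(0, σ²_a K)` with the VanRaden kinship `K = X_c X_c'/c`,
`c = Σ_k 2p_k(1−p_k)` and `σ²_a = c σ²_β`.  REML for `(σ²_a, σ²_e)` profiles
the restricted likelihood over the ratio `δ = σ²_e/σ²_a`:

* the kernel is projected onto an explicit orthonormal complement of the
  intercept (a QR basis, exact under rank deficiency), eigendecomposed once,
  and the 1-D profiled criterion is minimized on a log grid over
  `δ ∈ [1e−9, 1e9]` (61 points) followed by bounded Brent refinement
  (`xatol = 1e−10`);
* degenerate inputs (constant phenotype, zero kinship scale) raise errors.

The BLUP of `β` is then ridge regression with unpenalized intercept at
`λ = c σ²_e/σ²_a`.  Note the ratio: the residual-to-additive variance ratio,
the convention also used by the standard rrBLUP software; the inverse form
sometimes printed in the literature appears to be a typographical slip, since
only `λ = c σ²_e/σ²_a` makes ridge, rrBLUP and GBLUP coincide — an identity
the tests verify to 1e−6.  Because predictions are invariant to the kinship
scale `c`, generic feature matrices (e.g. interaction expansions) use the
trace normalization `c = tr(X_c X_c')/n` instead of the allele-frequency
form; only the reported variance components depend on this choice.

Narrow-sense heritability is reported as `h² = σ²_a/(σ²_a + σ²_e)` from the
GBLUP REML fit, clamped to [0, 1].

### Epistasis rrBLUP

The feature set is the `k` raw markers plus all `k(k−1)/2` pairwise products
`x_i ∘ x_j` (raw, uncentered dosages; centering happens inside the solver).
The implicit solver uses the closed-form Gram identity

    K = M + (M ∘ M − M₂)/2,   M = XX',  M₂ = (X∘X)(X∘X)',

so the kernel system is assembled in `O(n²)` memory without materializing the
interaction columns; the explicit solver materializes them (blockwise, with a
configurable feature cap) and reuses the rrBLUP machinery.  Both agree to
1e−5 on predictions by construction, which the tests check.

### Bayesian samplers

Single-site Gibbs with a maintained residual vector; all chains are
deterministic given the config seed.  Priors are not canonical for these
models and are explicit package choices:

* marker variances `σ²_ak ~ scaled-inv-χ²(ν, S)` with `ν = 4.2` and `S` set
  so the prior mean marker variance equals `0.5·Var(y)/Σ 2p_k(1−p_k)`
  (a heritability-0.5 heuristic);
* residual variance `σ²_e ~ scaled-inv-χ²(4, S_e)` with prior mean
  `Var(y)/2`;
* Bayes B: fixed `π = 0.05` by default (π = 1 recovers Bayes A and is
  permitted); Bayes Cπ: `π ~ Beta(1, 1)`, updated from its conjugate full
  conditional given the inclusion count;
* indicators are drawn from the collapsed (β integrated out) likelihood
  ratio, avoiding the reducibility of naive joint sampling at `β_k = 0`;
* Bayesian LASSO follows the Park–Casella hierarchy
  (`β_k | τ²_k ~ N(0, σ²_e τ²_k)`, `1/τ²_k` inverse-Gaussian,
  `λ² ~ Gamma(0.1, 0.1)` updated by Gibbs unless fixed).

Chain defaults are `n_iter = 10,000`, `burn_in = 2,000`, `thin = 5` —
deliberately desk-scale and shorter than publication-grade chains; the test
suite and the acceptance script use 600–800 iterations, which suffice for
the posterior-mean point predictions (GEBVs) these models are scored on.
An initial-positive-sequence effective sample size and a Geweke z-score for
the `σ²_e` trace are reported as diagnostics (flags, not hard failures).
Prediction uses posterior-mean effects.

### Elastic Net, LASSO, FoBa

The Elastic Net is parameterized by the **number of selected predictors**
(sparsity) and the grouping penalty λ₂, matching the LARS-EN convention in
which each sparsity level corresponds to a unique λ₁.  The path is computed
by LARS on the ridge-augmented system `[X; √λ₂·I]`, which has the identical
objective; the solution is read off the first path point with the requested
support size.  λ₂ = 0 is the plain LASSO, which cannot select more than
`min(n−1, p)` predictors (enforced with an explicit error).  Predictors are
standardized to unit variance by default.  Tests check every path point
against an independent proximal-gradient (FISTA) solver and the KKT
subgradient conditions.

FoBa adds, at each forward step, the feature with the largest exact
squared-error decrease (computed by orthogonalizing candidates against the
active set; ties break to the lowest column index), then takes backward
steps removing the feature whose removal raises the SSE least, as long as
that increase is at most `backward_tolerance × the last forward gain`.  The
default tolerance is 0.5 — the "adaptive" spirit quantified, since the
original description does not fix a value.  The forward loop stops at
`max_features` or when the best gain falls below `1e−10·‖y_c‖²`.

### ε-SVR

The standard two-sided ε-insensitive loss with the libsvm kernel menu
(linear, polynomial `(γu'v + r)^d`, radial `exp(−γ‖u−v‖²)`, sigmoid
`tanh(γu'v + r)`).  The margin-style constraint occasionally printed for SVR
is the classification form; the regression dual solved here has box
constraints `[0, C]` and the equality constraint `Σ(α−α*) = 0`, and a tiny
instance is checked against a generic SLSQP quadratic-programming oracle.
Defaults mirror common practice: `γ = 1/p`, `r = 0`, `d = 3`, `C = 1`,
`ε = 0.1`, features standardized.

### mRMR, SIS/ISIS, PCA-FOBA

Mutual information is the plug-in estimator in natural log.
Marker–phenotype relevance discretizes the trait to `{−1, 0, 1}` by z-score
thresholding at ±1 (sample sd, ddof = 1; a constant trait maps to all
zeros); marker–marker redundancy uses the raw dosage alphabet directly.
mRMR greedily maximizes `I(x_j; c) − mean_{i∈S} I(x_j; x_i)`; ties break to
the lowest marker index.  The prediction method (mRMR-GS) tunes the target
size by an internal 10-fold CV on the training fold — one mRMR run per inner
fold up to the largest candidate, scoring the selection-order prefixes — and
refits rrBLUP on the winning selection.  Candidate sizes default to
`{10, 25, 50, 100, 250, 500} ∩ [1, p]`.  Selection is training-fold-only by
default; a transductive switch adds unlabeled test genotypes to the
redundancy estimation (both readings of the method appear in the
literature; the training-only contract is the default here).

SIS screens by `|X'y|` on unit-variance columns (T clamped to p with a
warning); ISIS iterates on ridge residuals, pooling the union (default
3 iterations; the ridge penalty comes from a small internal CV grid when not
fixed).  PCA-FOBA is transductive by contract: components are computed on
the stacked train + unlabeled test matrix, keeping `min(n_total, p)` of
them, and FoBa runs on the training-row scores; calling `fit` without the
unlabeled matrix is an error.

## The simulator

The generator emulates the published structure of the QTLMAS 2010
population: 20 founders (5 male, 15 female), discrete generations (F0–F4 by
default), five chromosomes of 100 Mbp, biallelic SNPs.  Only these
structural facts are public; the remaining design is the package's own:

* founder alleles Bernoulli(p) per haplotype with `p ~ U(0.05, 0.5)` per
  marker; markers evenly spaced, remainder to the first chromosomes;
* random sire/dam mating with replacement within the previous generation
  (the true mating design is not published); offspring sexes random with
  both sexes forced present;
* Haldane recombination (no interference): crossover counts Poisson with
  mean = chromosome length in Morgans at a uniform 1 cM/Mbp, positions
  uniform;
* architectures: oligogenic (5 QTL, N(0,1) effects), polygenic (30% of
  markers, N(0, 1/n_qtl) effects), epistatic (oligogenic plus pairwise
  raw-dosage product interactions — matching the interaction features the
  epistasis solver uses);
* noise calibrated so `Var(additive)/(Var(additive) + σ²_e)` equals the
  target h² (realized, not expected, additive variance); with epistasis the
  realized narrow-sense h² is accordingly below the target;
* binary traits by thresholding the liability at an empirical quantile
  (default the median).

The default "qtlmas-mini" profile uses 1,000 markers and 4 × 100 offspring —
a deliberate desk-scale stand-in for the original 10,031 markers and ~3,200
individuals.  What the simulator does **not** emulate: coalescent founder
haplotype structure, selection or assortative mating, genotyping error and
missingness patterns of real arrays, sex chromosomes.  Passing tests
therefore demonstrate correctness of the methods and protocol under
idealized Mendelian data, not performance claims about any real population.

## Evaluation protocol

Folds are a seeded uniform permutation assigned round-robin, so fold sizes
differ by at most one and the partition is reproducible from
`(sample list, k, seed)`; one partition is shared by every method on a
dataset.  Signed r² is computed on the concatenated out-of-fold predictions;
a zero-variance prediction vector scores 0 by convention (the correlation is
undefined and a constant predictor carries no ranking information) and a
constant truth is an error.  The overfitting gap is reported as
`global − 10CV` (positive = optimism).  Min–max normalization maps each
dataset column to [0, 1]; an exactly constant column maps to 0.5 rather than
fabricating a best and a worst method.  Binary traits are scored by raw
signed r² against the 0/1 labels, the same as quantitative traits.

The stability ratio at level k counts features selected in at least k of the
K folds, divided by the size of the selection union — per feature, so two
features each present in 8 folds need not share those folds.

Relevance profiles rank `I(x_j; c)` (the mRMR relevance term) across
markers; the concentration statistic is the mean of the top-5 scores over
the overall mean.  A caveat measured by the test suite: the plug-in MI
estimator gives every null marker a small positive score, and the
top-5/mean ratio of a few hundred such noisy estimates sits near 3 even for
a trait with no concentrated signal.  Absolute flatness thresholds below
that floor are therefore not meaningful at this scale; the test suite checks
the oligogenic-vs-infinitesimal *contrast* instead.

## Preprocessing

Markers are filtered by missing-call fraction (default: drop markers with
more than 10% missing — stated inconsistently across dataset descriptions in
the literature, so the package exposes a single `max_missing_rate`
parameter), minor allele frequency, and monomorphism.  Missing dosages are
imputed by the per-marker mode (deterministic; haplotype-model imputation is
out of scope).  Population-structure correction regresses the phenotype on
an intercept plus the leading principal components of the column-centered
(not scaled) dosage matrix (default 4 components) and returns the zero-mean
residuals.  Dosages count minor-allele copies; positions are 1-based base
pairs; missing values are written as "NA".

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise every
claim while staying desk-scale: equivalences at 100 × 500 and 80 × 60,
heritability recovery at n = 500, p = 2000 (20 and 8 replicates
respectively), Bayes Cπ sparsity recovery at n = 500, p = 1000, and the
method-ordering comparison on 320 × 200 profiles (20 and 10 replicates).
These sizes are the package's own defaults for its bundled studies; all are
configurable.

## Known limitations

* MCMC chains at the desk-scale defaults are adequate for posterior-mean
  GEBVs but not for tail summaries of the posterior.
* The Elastic Net path relies on LARS; for `p` in the tens of thousands a
  coordinate-descent path would be faster.
* The implicit epistasis solver is exact but `O(n²)` in memory; it targets
  single-machine scale.
* The plug-in MI estimator is biased upward at small n; no bias correction
  is applied (none is standard for this protocol).
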
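# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the limitations of `gsel`, in enough detail that a maintainer
can judge what the tests do and do not establish.

## Mixed-model core

All ridge-type fits reduce to the single-kernel model
`y = 1μ + g + e`, `g ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`. One
eigendecomposition `K = U D U′` turns the restricted likelihood into a
smooth 1-D function of the variance ratio `δ = σ²_e/σ²_g`; μ is profiled out
by GLS at each δ. The optimiser is bounded scalar minimisation over
`log δ` (search window e^±18 around the kernel's mean eigenvalue, `xatol`
1e−10, ≤200 evaluations), followed by bisection on the analytic gradient of
the profiled criterion. The polish step matters: a derivative-free argmin
is limited to ~√ε accuracy in δ by floating-point noise in the likelihood,
which propagates to GEBV discrepancies of order 1e−6 between the RRBLUP
(`K = W W′`) and GBLUP (`K = G`) parameterisations of the same fit; the
gradient root is locatable to ~1e−12, bringing the two parameterisations'
GEBVs into agreement at machine precision. The same REML core serves
`fit_rrblup`, `fit_gblup` and `genomic_h2`, so variance components are
internally consistent across the package.

Degenerate inputs: a zero-variance phenotype returns σ²_g = 0 and flat
GEBVs; a REML optimum at the boundary (δ → ∞) yields zero marker effects.
The intercept is always fitted as a fixed effect by GLS, not absorbed by
centering the phenotype.

## Bayesian ridge regression

The Gibbs sampler cycles μ, each marker effect β_j in fixed column order
(scalar updates with a running residual), then σ²_β and σ²_e from
scaled-inverse-χ² full conditionals. Hyperpriors: df 5 on both variances;
prior scales split the sample phenotypic variance 50/50 between the marker
term (divided by the mean column sum of squares) and the residual. Chains
default to 1,000 iterations with 200 burn-in; posterior means are reported.
With the two variances frozen (degenerate priors) the stationary
distribution of the effects is exactly Gaussian around the ridge solution,
which is the sampler's correctness oracle: after 5,000 draws the posterior
mean agrees with the ridge solution within Monte-Carlo error. That check
is applied at the level of the whole effect vector
(‖posterior mean − ridge‖ ≤ 3·‖MC SE‖ in quadrature, with batch-means
standard errors) plus a 5-SE marker-wise bound — a strict 3-SE bound on
every one of 200 markers would fail by chance alone in a large fraction of
correct runs (the expected maximum of 200 standard-normal deviates is ≈ 2.9).

## Machine-learning stage

Random forest and MLP regressors come from scikit-learn; `max_features
"auto"` is interpreted as all features (the regression convention), and the
"linear" activation maps to identity. The 1-D CNN is implemented directly
in numpy — input → conv → relu → mean-pool → conv → relu → mean-pool →
flatten → dropout(0.2) → dense → relu → dropout(0.2) → dense(1) — trained
with mini-batch Adam on MSE, fully seeded. Mean pooling (one of the
standard pooling reductions) keeps the backward pass exact and
deterministic. Hyperparameter search holds out 20% of the training data,
scores each grid point by validation MSE, and refits the winner on the full
training set; the desk-scale default grids are small subsets of the full
enumerated grids (`FULL_GRIDS`), which remain available behind
`MLModelSpec(full_grid=True)`. Grid search runs once per trait, not per
CV fold — the tuning data therefore overlaps the CV folds; this mirrors
common practice at panel scale and is documented rather than hidden, since
the alternative multiplies runtime by the grid size times k.

At a few hundred training records the CNN generalises weakly (it can fit
the training panel nearly perfectly while transferring little to held-out
individuals); this is a property of small-n deep models, not a defect of
the implementation, and is why the ridge family is the default model set.

## Synthetic panel

* **Genotypes.** Each haplotype is a stationary AR(1) Gaussian process
  along the chromosome (coefficient `ld_decay_rho`), thresholded at the
  per-marker allele-frequency quantile; two independent haplotypes sum to
  the dosage. LD between markers j and j+d in latent space is ρ^d, so r²
  decays geometrically with marker distance and is positionable on a bp
  map. Defaults — 204 individuals, 12 chromosomes × 250 markers at ~45 kb
  spacing, ρ = 0.9, MAF ~ U(0.05, 0.5) — give multi-megabase LD blocks of
  the order reported for pepper diversity panels, at a marker density that
  keeps the default suite fast. What the generator does *not* emulate:
  population structure and admixture, coalescent allele-frequency spectra,
  selection/drift history, dominance and epistasis, multi-allelic sites.
  Tests passing on this generator therefore certify the estimators'
  self-consistency and calibration under a clean additive model, not their
  behaviour under confounded structure.
* **Traits.** `n_qtl` markers are drawn uniformly; effects are N(0,1) on
  centered dosages (the infinitesimal-model assumption of the ridge
  predictors); the residual SD is solved from the realized Var(BV) so that
  Var(BV)/Var(phenotype) hits the target h² in expectation. At target
  h² = 0 the phenotype is pure noise while breeding values are retained
  for oracle use; at h² = 1 the phenotype equals the breeding value.
* **Multi-environment trials.** Per-environment values add a genotype ×
  environment deviation with σ²_GE = `gxe_ratio`·σ²_G (default ratio 0.3,
  a mid-range value for yield traits in two-location trials) and a plot
  residual solved from the target `H² = σ²_G/(σ²_G + σ²_GE/n + σ²_e/nr)`;
  targets above `σ²_G/(σ²_G + σ²_GE/n)` are rejected as infeasible. The
  adjusted ("BLUP-like") value shrinks each genotype's across-environment
  mean toward the grand mean by the realized H² — an emulation of the
  statistical structure of an augmented-design BLUP (shrinkage toward the
  mean, noise level set by H²), not a reproduction of one.

## Genotype handling

Dosages count the alphabetically second listed allele (a fixed, arbitrary
convention; every model centers the dosage matrix, so allele flips are
affine and leave kinship, GEBVs and accuracies invariant — this invariance
is tested). QC order is sample call rate → marker call rate → MAF, with
MAF computed on non-missing calls; thresholds are exclusive ("< 0.01"
removed, exactly 0.01 kept). Removing low-call-rate samples first prevents
them from dragging marker call rates below threshold. Missing dosages are
mean-imputed per marker; imputation refuses all-missing markers (QC must
remove them first). Coordinates are 1-based; window arithmetic is raw bp.

## LD pruning

r² is the squared Pearson correlation of dosage vectors (genotypic LD), by
default on mean-imputed dosages via unit-normalised columns, with a
pairwise-complete mode behind a flag. The pruning scan is greedy and
deterministic: per chromosome in position order, a marker is dropped iff it
exceeds `r2_max` against an already-retained marker within `window_bp`
(leftmost-first retention as the tie-break). The published tool family's
exact step/window sub-parameters are unstated, so the audited
post-condition — an exhaustive re-scan of the retained set finds no
violating pair — is the contract, and `audit_prune` runs on every synthetic
instance in the tests. Constant markers have undefined r² and are treated
as not-in-LD. Retained count is monotone non-decreasing in `r2_max`;
`r2_max = 1` is the identity.

## Cross-validated accuracy

Folds partition the panel into k groups whose sizes differ by at most one
(204 individuals → four folds of 21, six of 20). Per iteration the model
is refit k times; held-out predictions are pooled and a single Pearson r
against the adjusted phenotypes is recorded (default 10 iterations; the
per-fold-average estimator is available via `accuracy_mode="per_fold"` but
is unstable at ~20 individuals per fold). Pooled predictions are expressed
as deviations from each fold's fitted intercept: pooling raw predictions
lets the k fold intercepts inject fold-mean noise that drives the pooled
correlation systematically negative on null traits, while a zero-signal
fit then yields exactly constant predictions, which are recorded as
accuracy 0 with a warning (the same convention used for any undefined
correlation, keeping iteration counts balanced).

Even with intercept-centering, the pooled estimator retains a small
negative finite-sample bias under *label permutation* of a fixed phenotype
vector (permuting a finite multiset induces Cov(y_i, y_j) = −σ²/(n−1)
between individuals, which flows through the kinship smoother); measured at
about −0.09 for n = 160, k = 10 and about −0.04 at n = 300. The
permutation-null checks therefore run at n = 300 and average over fresh
permutations; the per-fold estimator is unbiased under the null at any n.

Marker-set comparisons use the classic pooled-variance two-sample Student
t-test on per-iteration accuracy vectors (identical vectors → t = 0,
p = 1; zero within-group variance with different means → ±∞, p = 0 by
convention). Heritability-accuracy association uses Spearman's ρ with
mid-rank ties; recomputing it from the reference panel's printed (2-dp)
per-model accuracies gives ρ = 0.699, slightly below the 0.72 reported
from unrounded values — the package reports its own mid-rank computation
and does not force agreement.

## Selection response

`S` is the realized selection differential (selected-set phenotypic mean
minus population mean — for GS the set is chosen on GEBVs but S is always
measured on the phenotypic scale) and `R = H²·S`. Selection takes the
⌊fraction·N⌋ (≥1) highest-scoring candidates, ties at the cutoff resolving
to the lexicographically smaller id; a direction flag supports
lower-is-better traits. PS+GS is the intersection of the PS and GS top
sets. Percent change relative to PS is computed, by default, from R values
rounded to two decimals and rounded to the nearest integer percent: this
is the only convention under which small published response tables are
internally consistent (with exact arithmetic H² cancels and the percent
change reduces to the S-ratio, giving e.g. −63% where the rounded
convention gives −67%); `rounded=False` switches to exact arithmetic. The
reference panel's response table carries H² = 0.32 for mature red yield,
which its printed R values require, even though the accuracy table's
footnote lists 0.20 for the same trait; the package uses each table's own
inputs for each computation.

## Problem sizes and tolerances

The standing test suite runs the RRBLUP≡GBLUP identity on 21 instances
(n = 100–300, m = 500–2000, h² ∈ {0.2, 0.5, 0.8}; tolerance 1e−6, observed
~1e−13), heritability recovery at n = 500, m = 2000 over 20 replicates
(mean |ĥ² − 0.5| ≤ 0.05), the likelihood-grid oracle at 0.001 resolution
(agreement within 0.01), the Gibbs-vs-ridge check on a 60 × 200 instance
with 5,000 draws, pruning audits on ~1,200-marker high-LD panels, and CV
accuracy monotonicity in h² over 20 replicates at n = 160. These sizes
were chosen so the full suite completes in a few minutes on one core while
keeping Monte-Carlo error well inside each tolerance.

## Known limitations

* Single-kernel models only: no multi-kernel or G×E-kernel genomic
  heritability, no dominance/epistatic kernels, no pedigree A-matrices.
* The augmented-design BLUP emulation is a shrunken mean, not a fitted
  incomplete-block model; trial variance components for real data are
  accepted as inputs, not estimated.
* The Gibbs sampler updates effects marker-by-marker; for m ≫ 10⁴ a
  blocked or residual-update-free sampler would be preferable.
* `window_prune` reproduces the greedy windowed scheme's contract, not any
  specific tool's marker-step internals, so retained-set sizes need not
  match other implementations marker-for-marker.
* CV accuracy on small panels is a noisy, slightly biased estimator (see
  above); conclusions about model rankings should average over iterations
  and replicates, as the drivers do.
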
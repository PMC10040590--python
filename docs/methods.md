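# Methods

This note documents the statistical models implemented in `gspred`, the
numerical choices behind the samplers, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
methodology left room.

## Phenotype adjustment

Plot data follow a randomized complete block design per environment. The
two-variance mixed model y_io = μ + g_i + b_o + ε_io (genotype fixed,
block random) is fitted per trait and environment by EM-REML on the
mixed-model equations, converged when both variance estimates move by less
than 1e-8 (at most 500 iterations). The line-mean parameterization of the
fixed effects makes the reported BLUEs coding-invariant: they are the
generalized-least-squares line means, so with complete balanced data they
equal arithmetic line means regardless of the block variance. With fewer
than two blocks the block variance is unidentifiable; raw line means are
returned and flagged. Unbalanced (missing-plot) data go through the same
equations; no cell means are imputed.

## Marker handling

Quality control applies, in order: removal of entirely-missing columns,
a minor-allele-frequency filter (default MAF ≥ 0.05), a heterozygosity
filter (rate of code-1 calls ≤ 0.2), and LD pruning of near-duplicate
markers (squared Pearson correlation of gene contents ≥ 0.99) by a greedy
left-to-right scan within a 1000-marker sliding window, keeping the
earlier marker. The order and the greedy tie-break make QC deterministic.

Missing genotypes are mean-imputed per marker before any model use —
adequate for relationship matrices, and deliberately the only imputation
offered. Standardization uses the sample mean and sample sd (ddof = 1)
of the observed codes; a Hardy–Weinberg variant (center 2p, scale
√(2p(1−p))) is available behind a flag for interoperability. Kernel
construction: G = WW′/m on standardized markers; the Gaussian kernel uses
squared Euclidean distances between standardized marker rows with no
mean-distance scaling (a flag enables it). Eigenvalues in
(−1e-8·λ_max, 0) are clipped to zero; anything lower raises, since a
genuinely indefinite kernel indicates corrupted input.

The variable-selection models run on column-centered raw 0/1/2 codes
(no variance scaling), keeping effects on the natural per-allele scale;
`standardize=True` switches to unit-variance columns, which is required
for the exact GBLUP ≡ RR-BLUP correspondence (G must be built from the
same W the ridge model uses).

## Priors and Gibbs samplers

Every variance component has a scaled inverse-χ² prior with ν = 5.
Scales are elicited by mode matching from the sample phenotypic variance
V_y under the working assumption that the model explains r² = 0.5 of it:
S = V_target·(ν+2), with V_target = V_y·r²/mean(diag K) for kernel
variances, V_y·r²/MSx for marker-effect variances (MSx the summed sample
variance of the marker columns; BayesB divides additionally by 1−π so the
*expected* genetic variance matches), and V_y·(1−r²) for residuals. The
mixture proportion π = 0.99 is fixed, not sampled.

Kernel models are sampled in the eigenbasis of each kernel, computed
once: the genetic-value full conditional is then diagonal and one
iteration costs O(n²) for the basis rotations. Eigencomponents below
1e-10·λ_max carry no signal and are dropped. Unphenotyped lines never
enter the likelihood; their genetic values are the kernel conditional
mean K_new,obs K_obs⁻¹ û (pseudo-inverse via the retained eigenbasis).

Marker models use single-site Gibbs in fixed marker order with a running
residual, compiled with numba; the inclusion indicator is drawn with the
effect integrated out, then the effect from its conditional normal. The
M×E sampler is the same machinery with one main-effect sweep
(precision-weighted across environments, each with its own residual
variance) plus one specific-effect sweep per environment. Marker blocks
are centered and standardized per environment from the lines observed
there, so MSx equals the marker count and marker-scale variances convert
to the genetic-value scale by ×MSx, making h² and variance proportions
comparable with kernel-model estimates. The "half the phenotypic
variance" prior budget is split equally between the main and the specific
component.

The bivariate model samples the 2×n matrix of genetic values row-wise in
the eigenbasis of G (each row is an analytic 2×2 normal), covariances
from inverse-Wishart full conditionals with identity scale matrices and
ν_u = ν_ε = 4 (weakly informative, above dimension + 1), intercepts
jointly, and missing cells by data augmentation. Non-positive-definite
scale matrices are jittered (1e-8 on the diagonal) and the occurrences
counted. `residual_covariance="diagonal"` restricts Σ_ε to independence
between environments: the full matrix (default) can absorb
permanent-environment covariance shared across environments, which is
correct when such effects exist but dilutes r_g when they do not (e.g.
BLUEs from independent trials); the choice is the analyst's statement
about the error structure.

Chains default to 50,000 iterations, 20,000 burn-in, thinning 5
(`LONG_MCMC`); tests, cross-validation sweeps and the CLI default to
2,000 / 500 / 2 (`REDUCED_MCMC`), which is sufficient for posterior
means of variance components at panel sizes of a few hundred lines — the
conjugate-oracle and recovery tests quantify this. Burn-in and thinning
are applied to stored draws; only thinned post-burn-in draws are
summarized. Identical seeds give bit-identical chains (numpy PCG64
outside numba; numba's numpy-compatible RNG, seeded per call, inside).
Effective sample size and Geweke z are reported as diagnostics and never
gate anything.

## Cross-validation designs

Partitions are deterministic functions of (seed, replicate). The single
and CV1 designs mask the same random third of lines everywhere (training
size = floor(n·2/3)); CV2 splits lines into thirds — one masked in
environment 1, a disjoint one in environment 2 — so every masked cell's
line is observed in the other environment and both environments are
sparse at once; CV0 leaves out whole environments and uses the posterior
genetic values of the source environment directly (Pearson correlation is
location-free, so no target intercept is needed). Kernels are built from
genotypes only, so computing them once on all lines leaks no phenotype
information; phenotypes are masked per replicate. Model arms share
partitions and fit seeds, making comparisons paired. Undefined
correlations (constant vectors) are excluded from means and counted.

The corrected resampled t-test uses t = d̄/√((1/K + n_tst/n_trn)·s²_d)
with K−1 degrees of freedom, the overlap-corrected variance for repeated
random subsampling; the n_tst/n_trn ratio comes from the configured split.
Degenerate zero-variance differences give t = 0, p = 1 (zero mean) or
±∞, p = 0 (nonzero mean). Its type-I error is verified on
heritability-zero traits with two equal-skill ridge arms differing only in
shrinkage intensity: that pairing is an exact null *and* preserves the
training-set-overlap correlation the correction is designed for, whereas
arms with disjoint training halves make the correction wildly
conservative and arms with disjoint marker halves carry genuine
dataset-level skill gaps.

## Synthetic data

The generator emulates a two-environment diversity-panel trial:

* **Genotypes** — independent biallelic markers, allele frequencies
  uniform on [0.05, 0.5], calls Binomial(2, p) mixed with fully
  homozygous calls at an inbreeding coefficient F = 0.95. The high F
  reflects a predominantly selfing crop; it keeps marker heterozygosity
  far below the 0.2 QC cutoff, as in real landrace panels. Markers are
  linkage-free — enough for every statistical property tested here; LD
  pruning is exercised on constructed duplicate columns instead.
* **Genetic architecture** — marker effects on standardized gene contents
  split into a main component with variance share r_g and
  environment-specific components with share 1−r_g of unit total genetic
  variance, so r_g is the expected between-environment genetic
  correlation (realized correlation is stored). An optional fraction
  π_true of markers is forced to zero effect for variable-selection
  tests.
* **Phenotypes** — line-by-environment means are genetic value plus a
  residual that is drawn, residualized against the genetic values and
  rescaled, so var(g)/var(y) equals the target h² *exactly* per dataset;
  this keeps recovery tolerance bands tight. The field-trial layer adds
  a shared block effect N(0, σ²_b) and plot noise N(0, σ²_plot) around
  each mean in a complete RCBD with 7 and 5 blocks by default.

What the generator does **not** emulate: linkage disequilibrium and
population structure, genotype-calling error, non-Gaussian residuals,
selection, and correlated traits. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to the full messiness of field data.

## Problem sizes and tolerances

Statistical checks run at n = 120–300 lines and m = 200–1,000 markers
with the reduced chain profile — sizes at which every targeted effect
(conjugate agreement within 3 Monte-Carlo SEs, model identities at
correlation > 0.999, h² within ±0.1, r_g within ±0.15, CV2 gains ≥ 0.05)
is resolvable, chosen so the whole suite completes in about a minute.
Heritability recovery at n = 300 is near the information limit of the
design: unshrunk REML on identical data has a sampling sd of ~0.15,
against ~0.08 for the posterior mean under the 50%-rule prior, so the
±0.1 band is genuinely tight and the recovery test uses 4,000-iteration
chains to keep Monte-Carlo noise negligible against it.

## Known limitations

* The M×E model is additive; no dominance/epistasis terms and no
  environmental-covariate (reaction-norm) extension.
* The bivariate model handles exactly two environments; the M×E model
  handles any L ≥ 2.
* π is fixed; BayesA / Bayesian LASSO are out of scope.
* Imputation is marker-mean only; no phasing, no pedigree matrices.
* The LD pruning window is positional, which assumes markers are ordered
  along the genome.
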
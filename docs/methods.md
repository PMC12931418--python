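# Methods

## Model

`protride` detects sample–protein pairs whose measured abundance is
inconsistent with the rest of a cohort after accounting for known and hidden
sources of covariation.

**Preprocessing.** Raw intensities (proteins × samples, positive, missing
allowed) are normalized by median-of-ratios size factors computed on the raw
scale: the per-protein reference is the geometric mean across samples over
proteins observed everywhere (falling back to pairwise-complete geometric
means with a warning when no protein is complete), and each sample's factor
is its median ratio to that reference. Values are divided by the sample
factor and log2-transformed; proteins whose missing fraction strictly
exceeds a threshold (default 30%) are removed. Log base 2 was chosen so that
reported fold changes are `2^(x − x̂)`, the convention used for quantities
like "61-fold reduced". Size factors are computed before the log transform
because median-of-ratios is defined on the raw scale. Note that
median-of-ratios is equivariant only up to a global constant: rescaling one
sample by c shifts every normalized value by log2(c)/n through the
geometric-mean reference; relative structure is fully restored.

**Autoencoder.** The model reconstructs X (samples × proteins) through a
bottleneck of width q. Missing cells are set to protein means in the input
and excluded from the reconstruction loss. Optionally the binary presence
mask M is stacked onto the encoder input and a separate decoder head
predicts presence probabilities M̂ through a sigmoid; known covariates
(one-hot categoricals, standardized numerics) are concatenated to the
encoder input and to the latent code. The loss is

    L = MSE_observed(X, X̂) + λ · BCE_all(M, M̂),      λ = 1 by default,

with the BCE averaged over all cells (observed and missing) and sigmoid
outputs clipped at 1e-7 for stability. Optimization is full-batch Adam
(1e-4 for 1-layer models, 5e-4 for 2–3-layer ReLU stacks with geometrically
interpolated hidden widths) for 400 epochs. The implementation is pure
NumPy with hand-written backpropagation; the loss path and gradients are
verified in the test suite against closed forms.

**Initialization.** One-layer (linear) models start from a truncated SVD of
the protein-centered, imputed matrix: encoder = top-q right singular
vectors, decoder = their transpose, decoder bias = protein means, so the
epoch-0 reconstruction equals the rank-q PCA reconstruction exactly. The
mask head starts at zero weights with bias logit(presence rate). When
covariates are supplied, the decoder's covariate block is first set by
per-protein least squares of the centered intensities on the centered
design matrix and the SVD is taken on the covariate-adjusted matrix. This
matters: at learning rate 1e-4 for 400 full-batch steps, Adam moves weights
by at most ~0.04, so the fit is dominated by its initialization;
zero-initialized covariate weights would leave the conditional path inert,
whereas the regression start devotes the latent space to hidden structure
from the outset.

**Residual statistics.** Residuals e = x − x̂ on observed cells are modeled
per protein. Gaussian tails use the protein-wise mean and unbiased sd.
The default is a Student's-t model with a shared degrees-of-freedom
parameter, fit in two passes: (1) per-protein 3-parameter maximum
likelihood (L-BFGS-B on (μ, log τ, log ν) with analytic gradients,
initialized at median / 1.48·MAD / ν = 10, ν bounded to [0.5, 1000],
moment-based restart then moment fallback on failure); (2) ν̂₀ = median of
the per-protein estimates, then per-protein (μ, τ) re-estimated at fixed
ν̂₀ with a vectorized EM whose iterations are monotone in the likelihood.
Per-protein ν estimation alone is numerically unstable at cohort-scale
sample counts; pooling the df is what makes the tails usable. Two-sided
tail probabilities are floored at 1e-300.

**Calling.** Tail probabilities are adjusted per sample over that sample's
observed proteins using `scipy.stats.false_discovery_control` (BY default;
c(m) = Σ 1/l — BH optional), truncated at 1, and cells with adjusted values
≤ 0.1 are flagged. These are model diagnostics ranked like p-values, not
hypothesis tests; calibration is established empirically (below).

**Dimension selection.** Two routes. (i) Optimal hard threshold: count
singular values of the centered matrix above ω(β)·median(σ), with
ω(β) ≈ 0.56β³ − 0.95β² + 1.82β + 1.43 (unknown-noise variant), β the aspect
ratio; applies to linear, unconditioned models. (ii) Grid search: at most 25
candidates (or half the sample size, if smaller) log-spaced in
[4, n/2], rounded with duplicates bumped to the nearest unused integer so
the count is preserved; for each candidate the data are corrupted with
artificial outliers (1 per 1000 observed cells), the model refit, and the
candidate with the highest average-precision recovery of the injected cells
wins (ties to the smallest q). The final model is refit on the uncorrupted
data. Injection follows x° = x + z·s_j with s_j the protein sd of the
uncorrupted matrix, |z| log-normal (log-mean 3, log-sd 1.6) and a fair sign.

**Modes.** `protrider` = covariates + mask modeling (+ grid search);
`lite` = linear, no covariates, no mask, OHT dimension; `pca` = projection
only, no training; `zscore` = protein-wise standardization with Gaussian
tails (the zscore mode always uses Gaussian tails regardless of the
configured distribution); `isolation` = per-protein isolation forests
(100 trees, seeded) whose anomaly scores replace tail probabilities for
ranking. Cross-validation (leave-one-out or 5-fold) selects the dimension
per training fold, trains with early stopping (20% validation split,
patience 10), fits the t model on training residuals, and scores held-out
samples with training-derived parameters.

## Synthetic data

The generator emulates TMT-style cohorts: log2 intensity = protein mean
(N(20, 2)) + latent factors × loadings + per-batch protein-wise offsets
(sd `batch_sd`) + sex effect + t(ν)-distributed noise with per-protein
log-normal scales; exponentiated and multiplied by log-normal sample size
factors. Missingness combines MCAR (5%) with a logistic intensity-dependent
dropout anchored at the 2nd percentile, emulating low-abundance dropout.
Defaults (50 samples, 500 proteins, latent rank 6, ν = 5, 5 batches,
batch sd 2.0, noise scale 0.3) produce raw within-batch Spearman
correlations above 0.6, mirroring strongly confounded cohorts. The
generator does not emulate reporter-ion chemistry, peptide-level effects,
shared-peptide ambiguity, or non-additive batch artifacts; passing tests
establish internal consistency and calibration under the model's own
assumptions, not performance on any real cohort.

Negative-control datasets resample residuals i.i.d. from a fitted t model
(e* ~ t(ν̂₀, μ̂_j, τ̂_j)), add them to the fitted predictions, reverse the
preprocessing, and copy the anchor's missingness pattern; they contain no
true outliers, so every downstream call is a false positive. The
calibration study (20 datasets of 50 × 500 by default; the acceptance
script uses exactly this) refits the entire pipeline — including ν̂₀ — on
each dataset and reports the mean per-sample-run false-positive proportion
(0 when no call is made). Under BY at 0.1 this proportion is well below
0.1; BH calls are a superset of BY calls.

## Benchmark design

Two injection regimes are used deliberately. Dimension selection keeps the
canonical heavy-tailed amplitudes (log-mean 3: median 20 protein-sds). For
the paired comparison against the Z-score baseline, amplitudes are moderate
(log-mean 1.5, log-sd 1.0, i.e. roughly 0.6–30 sd, the range of
biologically plausible aberrations). The reason is a desk-scale artifact:
at n ≤ 100 samples and p ≤ 2000 proteins, an injected cell tens of
standard deviations out carries a singular value exceeding the fixture's
structure singular values, so any SVD-anchored reconstruction dedicates a
latent direction to it (often memorizing the whole sample row) and the cell
becomes invisible to residual-based scoring, while a Z-score — whose
denominator the injection is scaled by — flags it trivially. With moderate
amplitudes no absorption occurs, and confounder correction shows its real
advantage: outliers a few marginal sds tall are glaring once batch variance
is removed but sit inside the Z-score noise floor.

For the same reason, cross-validated scoring carries a small systematic
edge (~0.02 AUPRC) over the transductive full-data fit on small fixtures:
held-out samples cannot leak their own outliers into the fit. The package
asserts comparability of the two rather than superiority of the full fit;
with cohort-scale data the full fit's larger training set dominates.

## Numerical choices and defaults

| parameter | default | notes |
|---|---|---|
| max missing fraction | 0.30 | strict inequality; filter before modeling |
| λ (mask loss weight) | 1.0 | performance flat over a wide range; 0 disables the mask head |
| epochs / learning rate | 400 / 1e-4 (1-layer), 5e-4 (multi-layer) | full batch; no early stopping outside CV |
| ν bounds / init | [0.5, 1000], ν=10, median/MAD start | robust against flat likelihoods |
| adjustment / cutoff | BY / 0.1 (inclusive) | BH behind a flag |
| injection freq / amplitudes | 1e-3, log-normal(3, 1.6), fair sign | grid-search scheme |
| sigmoid clip / tail floor | 1e-7 / 1e-300 | stability only |
| isolation forest | 100 trees, full subsample, seeded | per protein |

Ties in the grid-search argmax go to the smallest q. Constant covariate
columns are dropped with a warning. Zero-sd proteins are excluded from
injection and flagged in tail-probability computation. Every stochastic
stage draws its own child seed from the user seed via `SeedSequence`, so
toggling one stage leaves the others unchanged.

## Known limitations

- Residual means in the Gaussian path are plain observed-cell means, not
  outlier-trimmed; extreme cells therefore slightly inflate protein scale
  estimates under the Gaussian (the t path downweights them).
- The decoder's intensity and mask heads are independent; hidden-layer
  widths for deep variants are a geometric interpolation, one of several
  reasonable choices.
- Missing values are modeled but never themselves called as outliers.
- Cross-validation requires every protein to retain ≥ 10 observed training
  residuals per fold; small cohorts with heavy missingness will error.
- Fitting is transductive: a sample's own (extreme) values influence its
  expectation. At cohort scale this bias is small, but see the benchmark
  note above.
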
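# Methods

## The model

`conngrad` analyzes the spatial organization of functional connectivity
inside a region of interest (ROI) of a resting-state fMRI scan. Rather
than parcellating the ROI into discrete subregions, it estimates
*connectivity modes*: spatially continuous gradients along which the
whole-brain connectivity profile of the ROI voxels changes.

Per subject, the chain is:

1. **Time-series extraction.** The 4D image is rearranged into a
   time-by-voxel matrix `A` over the ROI and `B` over the out-of-ROI
   voxels. Columns follow a fixed raster scan of voxel indices; voxel
   millimeter coordinates come from the image affine. Constant columns
   are dropped with a warning (they carry no connectivity information
   and would break correlation estimates).
2. **Lossless SVD reduction.** `B` is de-meaned column-wise and reduced
   to its singular-vector time series `B~` (all components with
   nonnegligible singular value retained, so `B~` spans exactly the
   signal subspace of `B`). This only rotates the out-of-ROI data;
   correlations with any voxel are preserved up to the basis change.
3. **Connectivity fingerprints.** `C[v, k]` = Pearson correlation of ROI
   voxel `v` with component `k` of `B~`. Pearson correlation makes the
   fingerprints scale-free, so `B` (and `A`) only need de-meaning, not
   variance normalization.
4. **Eta-squared similarity.** Fingerprint similarity between voxels `a`
   and `b` is

   `eta2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2] / sum_i[(a_i - M)^2 + (b_i - M)^2]`

   with `m_i = (a_i + b_i)/2` and `M` the mean of the `m_i`. Because the
   pairwise mean minimizes each pair's within-sum, within <= total and
   `S` is symmetric with unit diagonal and entries in [0, 1].
5. **Laplacian eigenmaps.** Graph weights are `W = S - min(S)` with zero
   diagonal (dense by default; a symmetrized k-nearest-neighbor option
   exists for large ROIs). With degree matrix `D` and Laplacian
   `L = D - W`, the generalized problem `L v = lambda D v` is solved via
   the symmetric normalized form `D^{-1/2} L D^{-1/2}`. Eigenvectors of
   the smallest *nonzero* eigenvalues are the connectivity modes; the
   constant zero-eigenvalue vector is discarded. `mode_index` counts
   modes in ascending eigenvalue order (1 = first-order, 2 =
   second-order). Modes are min-max rescaled to [0, 1]; eigenvector
   polarity is arbitrary, so each mode is sign-aligned against a group
   reference (negated iff its correlation with the reference is
   negative) before any cross-subject comparison.
6. **Group reference and QC.** The reference map is the iterative
   sign-align-then-average of all subjects' maps (stops when the
   polarity assignment stabilizes; at most 10 sweeps). An externally
   supplied reference map overrides the within-sample average. Subjects
   whose aligned mode correlates with the reference below 0.5 (strict)
   are excluded as low quality.
7. **Trend surface model (TSM).** The mode map is regressed on
   monomials `x^p, y^p, z^p` of the voxel coordinates for powers
   `p = 1..degree` (no cross terms, no intercept column; a degree-3
   model has 9 coefficients). Coordinates are z-scored per axis before
   raising to powers, and the monomial columns are de-meaned; the
   intercept is estimated separately and not reported among the
   coefficients. The fit is Bayesian linear regression with an
   isotropic zero-mean Gaussian prior: prior precision `alpha` and
   noise precision `beta` are set by evidence (type-II maximum
   likelihood) fixed-point iteration to relative tolerance 1e-6 (at
   most 200 sweeps). Pinning `alpha` near zero recovers ordinary least
   squares; tests use that limit as an oracle.
8. **Degree selection.** Models of degree 1..5 are fitted and the mean
   percent variance explained per degree forms a scree curve. The elbow
   is the interior degree after which the marginal gain collapses by
   the largest factor (max of `g_d / max(g_{d+1}, 0.1)` over interior
   degrees with gain above 0.1 percentage points). Curves with total
   range below 0.5 percentage points carry no degree signal and fall
   back to the lowest degree; ties break low. This rule reproduces the
   intended behavior on reference curves — e.g. (60, 85, 95, 96, 96.5)
   elects degree 3 — and is robust on saturating curves such as
   (56, 91, 99.8, 99.8, 99.8), where chord-distance rules mis-pick 2.
9. **Outlier screen.** With coefficients pooled over subjects, a
   subject is excluded iff any coefficient lies strictly beyond
   mean ± 3 sample SD (single pass, no re-screening after removal;
   zero-variance coefficients are skipped with a warning).
10. **Inference.** Group differences: likelihood-ratio test of nested
    logistic regressions of group on {age, gender} vs {age, gender, all
    TSM coefficients}; `chi2 = 2 (LL_full - LL_reduced)` with df = the
    number of coefficients, p from the asymptotic chi-square law, and
    in-sample classification accuracy at probability threshold 0.5
    (labeled in-sample; no cross-validation). Outcome associations:
    per-outcome multiple linear regression with the overall F-test,
    R-squared, row-wise deletion of missing outcomes. Significant
    associations get post-hoc per-coefficient partial correlations
    (double-residual method, controlling age, gender and the remaining
    coefficients; two-sided p from the t transform). Bonferroni
    families: group tests alpha = 0.05/4 = 0.0125, symptom models
    0.05/3, trait models 0.05/12. Contamination checks re-run the
    models with meanFD appended to the covariates and report the
    coefficient-by-{age, meanFD, DVARS} correlation table.

## Motion quality control

A subject is excluded when meanFD > 0.2 mm, when more than 20% of
frames exceed the spike threshold (default 0.25 mm, configurable), or
when any single framewise displacement exceeds 5 mm; every triggered
rule is recorded. The pipeline consumes FD summaries (preprocessing is
out of scope); `framewise_displacement` converts six realignment
parameters to Power-style FD (rotations as arc length on a 50 mm
sphere) for synthetic traces.

## The synthetic cohort generator

The generator plants a known gradient so that every downstream stage
can be validated against ground truth.

- **Geometry.** An ellipsoidal ROI (default semi-axes 4 x 3 x 3 voxels
  on a 20^3 grid of 3 mm voxels, ~150 voxels) plus 240 out-of-ROI
  voxels sampled outside a one-voxel guard zone. The affine is RAS with
  the grid center at the origin.
- **Signals.** `n_latent_signals` (default 4) stationary AR(1) Gaussian
  series (coefficient 0.4, unit variance) stand in for distinct
  "cortical" signal sources; the AR coefficient is a simple surrogate
  for BOLD autocorrelation. Out-of-ROI voxels are split into zones,
  each carrying one latent signal plus white noise.
- **Planted gradient.** Each ROI voxel mixes latent signals 1 and 2 as
  `(1 - g) s1 + g s2 + noise`, with `g = logistic(k u)` where `u` is
  the voxel's projection on the gradient axis rescaled to [-1, 1] over
  the ROI. `k` is therefore a dimensionless steepness. Group
  membership sets the mean of `k`: controls 6, patients 3 — patients
  show a more gradual spatial change in connectivity — with
  between-subject SD 0.5 (a free parameter; within-cohort variability
  of gradient shape is not well characterized empirically, so a
  moderate ~10% coefficient of variation was fixed once).
- **Noise.** `noise_sd = 0.5` against unit-variance latent signals
  (temporal SNR 2), reflecting that the analysis operates on smoothed,
  denoised time series; the similarity matrix further averages noise
  over components.
- **Traits and covariates.** Trait scores are `a k + e` with coupling
  `a = 2` and noise SD 1, mapped onto clinical anchor scales through
  the theoretical score SD (a fixed, data-independent
  standardization). With `a = 2` and SD(k) = 0.5 the steepness
  explains about half the trait variance within a homogeneous group.
  Clinician-rated symptom scores are generated for patients only;
  trait factor scores for everyone. Age is uniform on [18, 50] and
  gender Bernoulli(0.5), independent of group by default so covariate
  adjustment can be tested without confounding (`confound_age_by_group`
  couples them). meanFD is log-normal (median ~0.055 mm), independent
  of the gradients unless `motion_contaminated` couples it to `k` for
  testing the contamination checks.
- **Determinism.** All randomness flows from the config seed through
  spawned substreams; identical configs give bit-identical cohorts.

What the generator does *not* emulate: hemodynamic convolution, scanner
physics, realistic anatomy or atlas geometry, spatially structured
artifacts, or non-stationary motion. Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under the model's own
assumptions, not performance on real scans.

## Numerical choices

- SVD rank threshold: `max(shape) * eps * s_max` (standard numerical
  rank).
- Eigenvalue zero-tolerance 1e-10 separates the constant vector from
  genuine modes; a disconnected similarity graph (multiple zero
  eigenvalues) is an error rather than a silent multi-component
  embedding.
- Eigenvector polarity before alignment is canonicalized (largest
  centered element positive) so runs are bit-reproducible.
- `eta_squared_matrix` is evaluated from Gram-matrix identities
  (`within = ||a-b||^2/2`); a pair of identical constant fingerprints
  (zero denominator) is defined as similarity 1 with a warning.
- The evidence iteration works in the eigenbasis of `X'X`, making each
  sweep O(m); divergence (non-finite hyperparameters) raises with
  diagnostics, non-convergence only warns.
- A constant mode map short-circuits to zero coefficients and 0%
  variance explained (the threshold allows a few ulps of rounding in
  the mean).
- Logistic fits use bounded quasi-Newton (L-BFGS, tight tolerances).
  Perfectly separated data still yield a finite likelihood-ratio
  statistic and 100% in-sample accuracy; a warning flags suspected
  separation. Only a non-finite likelihood or a constant group label
  is an error.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on simulated
cohorts at desk scale, chosen as the package's own validation sizes:
cohorts of 27 + 56 subjects (~150-voxel ROI, 120 time points) for the
end-to-end analysis, 10 noise-free subjects for gradient recovery, 200
simulated cohorts of n = 40 for null calibration of the omnibus test,
100 cohorts for its power under the default group effect, and 500
permutations for the association-model calibration.

## Known limitations

- **Small-sample inflation of the omnibus test.** The likelihood-ratio
  statistic with 9 coefficient columns plus 2 covariates is referred to
  its asymptotic chi-square law. At n = 40 the null rejection rate at
  nominal 0.05 is ~0.17, at n = 80–85 ~0.09, approaching nominal only
  for n >= 100. This is a property of the test itself, faithfully
  reproduced; the package does not apply a small-sample correction.
  Interpret omnibus p-values at small n accordingly.
- **Rank recovery on saturated gradients.** When the planted logistic
  gradient saturates hard (steepness ~6), both plateaus form tight
  fingerprint clusters; the fine ordering of the eigenmap within a
  plateau is then numerically delicate, and roughly 1 in 60 noise-free
  subjects drops below 0.95 Spearman against the planted field even
  though the Pearson correlation stays above 0.95. kNN sparsification
  does not help here (it disconnects the plateau clusters), so the
  dense graph remains the default.
- Classification accuracy is in-sample and optimistic; it is reported
  for comparability, not as a validated classifier.
- The TSM basis omits cross terms (x*y etc.) by design; gradients
  oblique to all three axes are summarized only through their axis
  projections.
- Coordinate z-scoring before raising to powers is a monotone per-axis
  reparameterization; raw-millimeter coefficients are not directly
  comparable across differently sized ROIs (the standardization is
  recorded with every basis).
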
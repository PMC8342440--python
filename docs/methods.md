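# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the tests demonstrate.

## Pipeline overview

The analysis couples two high-dimensional views of the same subjects:

1. **Network features** (`netfeatures`).  Per-subject streamline-count
   matrices become connection-density matrices via
   `C_d = 2 s_ij / (n_i + n_j)` with `n_i` the parcel voxel counts.  A
   consensus threshold keeps an edge iff it is nonzero in a *strict
   majority* of subjects (`present > 0.5 n`; an edge in exactly half is
   removed).  Node degree is the binary count of surviving edges —
   configurable in principle but binary by default, since density weights
   carry scale artifacts and degree is the downstream feature.  Graph
   summaries (highest degree, edge density, binary global efficiency with
   disconnected pairs contributing 0) are fit with quadratic lifespan
   trends on decade-bin means (7 bins starting at 18 y, OLS on bin
   centers; AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), k = 3, n = bins).
   Binning before fitting is an assumption: per-subject fits would give
   the same curvature sign but very different R² and AICc scales.

2. **Normalization** (`prep`), fixed order: filter → z-score → deconfound
   → (behavior only) nearest-SPD covariance → PCA.
   - The outlier filter drops the whole *variable* when any observed cell
     is > 3 sample SDs from the variable mean, and any variable ≥ 50 %
     missing.
   - z-scoring uses the sample-SD convention (ddof = 1) on observed cells;
     missing cells stay missing.
   - Deconfounding replaces each variable by its OLS residual on
     [intercept | standardized confounds | optional age].  Missing cells
     are imputed at the variable mean (0 after z-scoring) for the fit and
     restored to missing afterwards — the minimal-leverage choice.
     Confounds default to height, weight, sex, heart rate, systolic and
     diastolic blood pressure; any supplied column list is accepted.
   - The behavior covariance is the pairwise-complete covariance projected
     to the Frobenius-nearest symmetric positive-definite matrix
     (Higham-style alternating projection, eigenvalue floor 1e−10: strict
     positive definiteness needs a positive floor).  Complete-data input
     is a fixed point.
   - PCA is an eigendecomposition of that covariance (behavior) or of the
     sample covariance (network); scores are the zero-imputed standardized
     data projected on the components.  Component signs are fixed
     deterministically (largest-magnitude element positive) so repeated
     runs are bit-identical.

3. **CCA** (`cca`).  Solved by SVD of the QR-whitened cross-covariance,
   equivalent to the generalized-eigenvalue formulation (tested against an
   independent eigen-solver to 1e−8).  Factor pairs are ordered by
   decreasing canonical correlation; the first pair is oriented so its
   combination correlates non-negatively with age when an orientation
   target is supplied, remaining pairs by a largest-weight-positive rule.
   `r_age` is reported unsigned (√R² discards sign).  Significance of
   `r_age` uses a resampling test that re-draws regressor rows with
   replacement, breaking their pairing with age (a pure-permutation option
   exists; the two agree closely and the with-replacement variant is the
   default).  Standard errors come from jointly resampling subjects.
   Type-I calibration at α = 0.05 lands at ~0.044 over 500 null
   simulations.

4. **Cross-validation** (`crossval`).  Each repeat partitions subjects
   into k = 5 near-equal folds; each fold is projected through *training*
   statistics only (z-score means/SDs, deconfounding coefficients, PCA
   components, CCA weights), so every subject gets one hold-out factor
   estimate per repeat.  Hold-out loadings are correlations of the
   reference-normalized data with the *assembled* full hold-out factor
   matrix (per-fold n would be too small for stable correlations).  Final
   estimates are element-wise medians across repeats, with across-repeat
   SDs as standard errors.

   **Factor alignment.** Canonical factors have arbitrary sign and can
   permute between fits, so each fold model is matched to a full-data
   reference model before accumulation — greedily, by largest |cosine|
   between weight vectors mapped to *variable space*
   (`components @ weights`).  Component-space weights are not comparable
   across folds: each fold's PCA basis carries its own sign convention and
   an arbitrary rotation of the noise subspace, and matching there
   demonstrably scrambles factors.  Variable-space matching recovers
   planted values exactly where component-space matching failed.

   The grid search evaluates cross-validated r_age for every PCA-pair in a
   range; each cell's CV seed is a pure function of (pair, master seed),
   so coarse grids and parallel execution reproduce the dense sweep's
   numbers cell-for-cell.  Ties break to the smallest brain, then
   behavior, component count.  Selecting the best cell and reporting its
   r_age from the same CV distribution is optimistically biased; the
   pipeline reproduces that procedure deliberately and this note is the
   caveat.

5. **Rich club** (`richclub`).  The group network is the mean density
   matrix with a simple-majority consensus threshold.  The core is the top
   `round(fraction · n)` nodes by min-max-normalized binary degree
   (ties to the lower node index); the default fraction 54/376 reproduces
   a 54-core / 322-periphery split on a 376-node network.  The
   participation coefficient here is the *ratio* of within-group to
   between-group connection counts — nonstandard but retained as the
   analysis defines it, with NaN (not infinity) when a node has no
   between-group edges and a standard within/total variant by flag.

6. **RSA** (`rsa`).  `S[u,v] = 1 − |Pearson corr|` between the two
   variables' loading profiles across all canonical factors.  Whole-row
   sign flips are absorbed by the absolute value; factor-*column* signs do
   change Pearson row correlations, which is why factor orientations are
   fixed deterministically upstream rather than patched here.  Module
   averaging excludes S's diagonal cells; a singleton module's self-pair
   is defined as 0 (its only cell is the diagonal).  `S_d = S₁ − S₂`
   contrasts the full model with the age-deconfounded variant: where age
   drives a coupling, loadings are similar in M₁ (low S₁) and decoupled in
   M₂ (high S₂), so age-driven module pairs show the most *negative* S_d.
   Chord data: r = 1 − S on the brain-to-behavior block, min-max
   normalized, entries at or below the 75th sample percentile (linear
   interpolation) eliminated, survivors transformed (r·1000)².

## The synthetic generator

`CohortSpec` defaults are the study conditions the pipeline is meant to
face: 594 subjects evenly sampled over 18–88 y (7 decade bins, counts per
bin differing by ≤ 1), 388 behavioral variables of which 20 are >50 %
missing and 34 carry an injected >3-SD cell (leaving 334 after filtering),
376-node connectomes, and half the behavior couplings increasing with the
latent axis.  The latent axis is the standardized negative squared
distance of age from a 40-y peak — an inverted U matching rise-then-fall
lifespan trajectories; behavior variable j is
`beta_j·latent + gamma_j'·confounds + eps` with uniform (bounded) noise.
Confound–age correlations are capped at |r| ≤ 0.3 so deconfounding cannot
silently absorb the signal of interest.  Streamline counts are Poisson
around a fixed group topology (a designated high-degree core, a
configurable set of rare edges that fail the consensus threshold) scaled
per subject by `1 + 0.5·latent`.  Everything derives from one integer
seed through `SeedSequence` spawning, one stream per component.

Residual-noise cells whose observed |z| would exceed 2.9 are redrawn, so
the injected outliers are the *only* cells that trip the 3-SD filter —
this keeps filter behavior exactly predictable from the truth record while
preserving the generative identity of every column.

Two calibration cohorts plant exact in-sample values by orthogonalizing
their noise components: `planted_axis_cohort` (cross-view correlation 0.6,
best achievable age association 0.65 — the view latents share a common
factor u with `corr(best combo, age) = c·sqrt(2·rho/(1+rho))`, solved for
c) and `module_coupled_cohort`, whose only cross-domain coupling is
*linear* in age and confined to two behavior domains × two network
modules, the mirror experiment for age deconfounding.  A quadratic latent
would survive linear-age removal; the linear construction is what makes
the M₂ contrast clean.

**What the generator does not emulate:** real marginal distributions
(lifespan-cohort data are typically skewed and heteroscedastic), informative
missingness, site or scanner effects, spatial autocorrelation of parcels,
or topology differences beyond a scaled core.  Passing tests demonstrate
that the machinery recovers planted structure under its own assumptions,
not that those assumptions hold for any particular real dataset.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale by choice: planted
recovery uses n = 600 subjects, 40 + 40 variables, 3 + 3 components and
100 CV repeats; the mirror experiment n = 400 with 15 repeats; null
calibration 500 simulations × 1,000 resamples.  Full-study scale (15,000
throws × 9,801 grid cells) is exposed through the same APIs — each grid
cell is an independent pure function, so the sweep parallelizes trivially
— but only its bookkeeping is exercised in tests.  Repeat counts of
10,000–15,000 are accepted parameters, never hard-coded.

## Known limitations

- Hold-out ρ₁ slightly underestimates the planted coupling (≈ 0.59 for a
  0.6 plant): variable noise attenuates any estimate of the view latents.
- Alignment of higher (noise) factors across folds is best-effort; their
  medians are not interpretable, and only the first axis feeds inference.
- The grid-search score is optimistically biased post-selection (above).
- The bootstrap-vs-permutation distinction in the null test is stated, not
  resolved; both options are implemented.
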
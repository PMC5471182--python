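# Methods

This note documents the statistical machinery implemented in `crypsis`,
the defaults it ships with, and the choices made where more than one
reasonable convention exists.

## The question and the model

Across a clade of related species, fur colouration may track the colour of
the occupied habitat (camouflage under predation pressure) or simply
resemble that of close relatives (phylogenetic inertia). The package
separates these signals for per-specimen colour data: fur RGB + total
reflectance as responses; habitat RGB + total reflectance, geographic
coordinates, collection/field origin and phylogenetic eigenvector scores
as predictors; partial least squares regression as the estimator, because
the predictor block is strongly collinear by construction (the four
habitat colour bands of reflectance imagery typically correlate above
0.85).

## Colorimetry

Colours live on the 8-bit reflectance scale (0–255). Balance correction is
the per-channel linear map sending the observed black reference to 0 and
the observed white reference to 255; values outside the range afterwards
(specular highlights, deep shadow) are clipped, and clipping is the only
non-linearity in the chain. Patch colour is the arithmetic channel mean
over a square region; because the balance map is linear, correcting then
averaging equals averaging then correcting except for clipped pixels.
Total reflectance uses the BT.601 luminance weights
`L = 0.299 R + 0.587 G + 0.114 B`, applied identically to fur and habitat
colours (one shared implementation). Continuous colour variables are
log10-transformed and z-scored (sample sd, n−1) before modelling.

## Habitat extraction

A `HabitatRaster` is three reflectance bands on a north-up regular grid
with an affine geotransform and a nodata sentinel; I/O is plain multi-band
TIFF with a JSON sidecar for the geotransform. Temporal stacks are
averaged per pixel, skipping nodata (a pixel is missing only if missing
everywhere). The habitat colour of a sample point is the mean of pixels
whose *centers* fall within the buffer radius (1 km by default, matching
the home-range scale of small desert rodents); if the radius captures no
center, the containing pixel is used. For rasters in geographic
coordinates the radius is interpreted in meters via local metric scaling
(one degree of longitude shrinks with cos latitude); properly projected
rasters are handled exactly. Consistency of habitat colour over time is
estimated by splitting the image series into two period groups, averaging
each, and treating the paired extractions as repeated measurements for the
ICC.

## Repeatability and classical tests

Repeatability is the one-way consistency ICC computed from the between-
and within-group mean squares of a balanced one-way ANOVA,
τ = (MSB − MSW)/(MSB + (k−1)·MSW) with F = MSB/MSW; k is 2 in both designs
the pipeline uses (re-sampled fur patches; two habitat periods). The
species effect on colour is the sequential (Type-I) F test with
origin/collection covariates entered first — "species, after sampling
artefacts". Partial Pearson correlations correlate OLS residuals of the
two variables on the covariate block, with the t distribution on
n − 2 − q degrees of freedom.

## Phylogenetic eigenvectors (PVR)

The patristic distance matrix D is square-root transformed and
double-centered, G = −½ J D J with J = I − 11′/n, then eigendecomposed.
The square-root convention matters: on an ultrametric tree the patristic
distance is a linear function of the Brownian covariance C
(d_ij = 2T − 2C_ij), so G = JCJ exactly, and a Brownian trait's
variance decomposes along the eigenvectors in proportion to their
eigenvalues. Centering the *squared* distances (plain PCoA) breaks this
identity and biases PSR curves visibly below the 1:1 line; it remains
available via `dist_transform="none"`. Eigenvalues below 1e−10 of the
maximum (and negative ones, which cannot occur for ultrametric input under
the sqrt convention) are dropped and counted. Eigenvector signs are fixed
by making each column's first non-negligible entry positive, so outputs
are reproducible across BLAS implementations.

Moran's I uses inverse-patristic-distance weights, row-standardized, zero
diagonal (configurable: `inverse-squared`, `binary-nn`). The statistic,
its null expectation −1/(n−1) and its variance under the normality
assumption follow the classical formulas; p-values are two-sided normal.
Eigenvector selection is greedy: while the residual autocorrelation of the
trait (after OLS on the selected vectors) is at or above the threshold
(default 0.06), add the vector whose inclusion minimises residual I, ties
broken by lower index. A perfect fit (zero residual variance) terminates
selection; exhausting the basis without reaching the threshold returns all
vectors with a warning flag rather than an error.

## PSR curves

For k = 1..m the trait is regressed on the first k eigenvectors
(descending eigenvalue); the curve plots R²(k) against the cumulative
eigenvalue fraction. Under Brownian motion the expected curve is the 1:1
line; the package reports the mean signed deviation and the signed
trapezoid area between curve and diagonal. Two calibration facts users
should know, both measured by the test suite: (i) even under Brownian
motion the *mean* deviation of a single simulated trait has a small
negative bias on strongly structured trees — R²(k) is a ratio of
correlated chi-square forms, and Jensen's inequality bites hardest when
one eigenvalue dominates; (ii) a white-noise (phylogeny-free) trait gives
negative deviations with high probability precisely because the cumulative
eigenvalue fraction runs above k/m on structured trees. The package ships
a balanced 14-taxon reference tree (three quartets plus a cherry, depth 1)
on which the Brownian mean deviation is ≈ −0.02 and white-noise deviations
are negative in ≈ 93% of draws.

## PLSR

`fit_plsr` implements NIPALS PLS2 on standardized X and Y: per component,
the inner loop alternates w ∝ X′u, t = Xw, c = Y′t/t′t, u = Yc/c′c to
convergence (tolerance 1e−10 on the relative change of t, cap 500
iterations); X is deflated by the loading p = X′t/t′t and Y by c.
When near-tied singular values of X′Y stall the power iteration (it
converges linearly at the ratio of the top two singular values), the loop
finishes with the exact fixed point — the dominant singular pair of the
current X′Y — instead of failing; the result is deterministic and equals
the converged iteration. Coefficients are recovered as
β = W(P′W)⁻¹C′; at A = rank(X) they equal multi-response OLS, which the
tests verify against the normal equations and scikit-learn.

Component retention uses Q²(a) = 1 − PRESS(a)/RSS(a−1) from k-fold
cross-validation (default 10 folds, stratified by species when available):
a component is kept while Q² ≥ 0.0975, the classical threshold, and the
selected A is the last retained index. Variable importance is the
variance-weighted squared weight, share_j = Σ_a w²_ja EV_a / Σ_a EV_a,
which reduces to w² when one component is retained; a predictor is
flagged important above a 5% share. Coefficient uncertainty comes from
case-resampling bootstrap (rows with replacement, refit at fixed A,
default B = 1000); p-values are two-sided normal approximations of
β/se, percentile intervals are also reported, and the replicate array is
kept so linear combinations — e.g. the habitat block total — can be
tested afterwards. The block-level test used in recovery checks averages
the block-total coefficient over the (standardized, strongly correlated)
response traits, mirroring the single synthetic-response column of a
multi-response model.

## Pipeline

`CamouflageAnalysis.fit()` chains: repeatability (when repeated
measurements or period pairs are present) → species ANOVA → species means
of origin-adjusted, log-standardized fur traits → PVR, per-trait PSR
curves and eigenvector selection → assignment of selected eigenvector
scores to specimens → global PLSR (one multi-response model and,
optionally, four single-response models) → per-species PLSR for species
with at least `per_species_min_n` specimens (default 21, i.e. n > 20;
within species the design drops the phylogeny block and any single-level
factors) → partial and residual fur–habitat correlations → a variance
partition that sums predictor importance shares within blocks (habitat,
geography, origin, phylogeny) and scales by the explained percentage.
All randomness (fold assignment, bootstrap) flows from one seed; reports
carry the config hash and seed, and identical configurations reproduce
byte-identical tables. `sensitivity_rerun` repeats the
phylogeny-dependent stages under an alternative topology and reports
per-predictor weight and importance-flag deltas.

The variance partition is an operationalization: headline numbers of the
form "phylogeny explains x%, habitat y%" depend on how importance is
grouped, and the report labels them as block-share × explained-variance.

## Synthetic data

The generator emulates the study design: a Yule tree (exponential waiting
times at total rate kλ; after the n-th lineage appears the process runs
one further interval so all pendant edges are positive); per-species
Brownian effects (σ² = 25 per unit depth by default, giving species
effects of sd ≈ 7 on the 0–255 scale); a habitat raster with a shared
east–west linear gradient per band (amplitudes 50/45/35 over a 500 km
domain, pixel 2 km, white noise sd 5) — east–west by default so the
habitat gradient is identifiable against the north–south latitude effect;
specimen locations drawn uniformly over the domain (species are spatially
exchangeable; optional `range_sd` clusters species into ranges); fur =
base + 0.5·(habitat − mean) − 3·(latitude − mean) + 8·1[field] +
BM(species) + N(0, 6), truncated to [0, 255]; ~20% field specimens, the
rest spread over five museum collections. Defaults yield ≈ 460 specimens
with per-species counts between 5 and 120 and a phylogeny:habitat
partition ratio of roughly 0.5–0.6. The generator also writes two
period-raster stacks (for habitat ICC) and can render per-specimen patch
images with white/black reference swatches under a known linear
distortion, which balance correction must invert.

What the synthetic data does *not* emulate: real substrate texture and
spatial autocorrelation of reflectance beyond a linear gradient, MODIS
cloud/QA artefacts, non-Brownian trait evolution, and measurement error
correlated across channels. Passing recovery tests therefore demonstrate
the statistical chain, not robustness to those data pathologies.

## Known limitations

- With species spatially clustered (`range_sd` set) and only ~14 species,
  chance correlation between Brownian species effects and species-mean
  habitat can make the habitat block appear important and
  bootstrap-significant in a sizeable fraction of null datasets: the
  case bootstrap resamples specimens, not species, so species-level
  confounding is pseudo-replicated. This is a property of the method at
  small clade sizes, not of the implementation; treat per-specimen
  bootstrap p-values for species-level contrasts with caution.
- The PSR Brownian calibration is exact only in expectation under the
  square-root/PCoA identity on ultrametric trees; non-ultrametric trees
  carry no such guarantee.
- The Moran's I p-value uses the normality approximation; permutation
  tests are easy to run from `morans_i` but are not the default.
- One-way consistency ICC only; two-way/agreement forms are out of scope.
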
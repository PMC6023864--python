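# Methods

## The problem being modelled

A species' *realized* climatic niche is observed through occurrence records
in one period; projecting a distribution model onto another period assumes
that niche was conserved. The package operationalizes the two standard ways
of interrogating that assumption: (i) *geographic* — calibrate models in
one scenario, transfer them to another, and ask whether independent
presences (fossil records) fall in the predicted suitable areas; and
(ii) *environmental* — compare the occupied regions of a common
environmental ordination directly, with overlap indices and randomization
tests. Both tracks operate on the same containers: a `ClimateStack` of
named bioclimatic grids per scenario and `OccurrenceSet` point records with
roles (presence, fossil, background, pseudoabsence).

## Synthetic data generator

The generator supplies the study conditions for every test.

* **Climate fields.** Each variable is seeded white noise low-pass filtered
  with a Gaussian kernel (`autocorr_length`, in cells) and restandardized,
  then mixed through the Cholesky factor of the requested cross-correlation
  matrix, then scaled to per-variable mean/SD. This gives controllable
  spatial autocorrelation and inter-variable correlation with no
  geostatistics machinery. In the default study the three temperature-like
  variables (bio4, bio8, bio9) have spatial SD 4 (a °C-like spread over a
  peninsula-sized domain) and the two precipitation-like variables
  (bio18, bio19) are positive-mean (5) unit-SD fields, so degree-valued
  offsets and fractional drying are both meaningful. The default
  autocorrelation length is 12 cells on an 80×80 domain (~15% of extent):
  interpolated bioclimatic rasters are dominated by smooth continental
  gradients, and rougher fields would place much of the map in climates
  absent from any realistic training sample.
* **Scenarios.** A paleo scenario is the current stack transformed cellwise
  by `value·factor + offset` per variable. Defaults: a mild mid-Holocene
  analogue (+1 on temperature variables, +5% precipitation), a glacial
  scenario (−5, +20%), and a warm/dry last-interglacial analogue (+3.8 on
  temperature variables, ×0.84 on precipitation — an average +3.8 degrees
  and −16% precipitation contrast). Only the interglacial contrast is
  anchored to reported climatology; the other presets are free parameters
  chosen to span mild, strongly non-analogous and warm/dry regimes.
* **Species truth.** Suitability is a Gaussian response
  `s(x) = s_max · exp(−½ Σ_j ((x_j − μ_j)/σ_j)²)` with `s_max = 0.9`.
  The default tolerance is half the spatial SD of each variable — a habitat
  specialist whose niche is clearly narrower than the available climate, as
  appropriate for a range-restricted endemic. Occurrences are distinct
  cells sampled without replacement with probability proportional to
  suitability: 404 current presences and 28/16/13 fossils for the three
  paleo scenarios, thinned to one record per grid cell. A *conserved*
  fossil record uses the same truth evaluated on the shifted climate; a
  *niche shift* moves the optimum by a configured displacement before
  sampling.
* **What the generator does not emulate.** Real topography, sampling bias,
  dispersal limitation, biotic interactions, and dating/placement error in
  fossil records. Passing tests therefore demonstrate the statistical
  machinery recovers known truth under clean conditions; they do not certify
  behaviour under the observational biases of real occurrence databases.

## Geographic track

* **Contrast samples.** Background = uniform sample of 20% of unmasked
  cells; pseudoabsences = uniform non-presence cells, default count equal to
  the number of presences (the count is a free parameter in the literature;
  equal class sizes keep the prevalence interpretable).
* **GLM.** Binomial logit via iteratively reweighted least squares
  (statsmodels) on per-variable powers 1..degree (default 2, no
  cross-products) of standardized variables. With a background contrast the
  contrast rows are weighted m/N so presence and contrast mass are equal.
  Complete separation (common when calibrating on a dozen fossil records)
  falls back to a tiny-ridge fit (L2 = 1e−6) and flags the model rather than
  failing.
* **Random forest.** scikit-learn regression forest (500 trees by default)
  on 0/1 labels; variance explained is the out-of-bag R². Permutation
  importance is the percent increase in MSE of forest predictions on the
  training table when one variable is shuffled (a constant variable scores
  exactly 0).
* **Maxent-like model.** Features are the background-standardized variables
  and their squares; the L1-penalized gain is maximized by splitting each
  coefficient into positive/negative parts (making the objective smooth)
  and running L-BFGS-B. The per-feature penalty is
  `reg_multiplier/√m` (m presences) on standardized features, the sample-
  variance scaling of the classic implementation absorbed by the
  standardization; the multiplier defaults to 3. Suitability output is the
  logistic transform of the linear score — a monotone transform, so AUC,
  Spearman comparisons and Schoener's D are unaffected by the choice.
* **Projection and clamping.** Cross-scenario projections truncate each
  variable to its training (min, max) by default, so out-of-range climates
  receive the range-edge response ("extrapolation to minimum values") rather
  than an uncontrolled polynomial tail. Nodata cells stay nodata.
* **Validation.** AUC is the rank-based Mann–Whitney statistic (ties count
  ½). Internal validation refits on 20 stratified 60/40 train/test splits;
  external validation scores the projected map at independent presences
  against a fresh uniform background sample drawn in the target scenario
  (the contrast used for fossil-based AUC is not standardized anywhere; a
  target-scenario background is the least informative choice).
* **MESS/MoD.** Per cell and variable, with f the percentage of reference
  values below the projected value: s = 2f for f ≤ 50, s = 2(100−f) for
  f ≥ 50, and linear extrapolations below the minimum / above the maximum
  (negative exactly when out of range). MESS is the minimum over variables,
  MoD its argmin with ties to the first variable in stack order.

## Environmental track

* **Ordination.** One PCA (first two axes) of the pooled standardized cells
  of *all* scenarios, so every entity is scored in the same space; loadings
  carry a deterministic sign convention (largest-magnitude loading
  positive). Exactly two axes are used.
* **Occupancy grids.** On an R×R grid (default 100) spanning the pooled
  background scores padded 5%, occurrence density o and environment density
  e are binned-histogram kernel estimates smoothed with a per-axis Gaussian
  of bandwidth `σ_axis · n^(−1/6)` (the 2-D Scott plug-in rule), kernel
  truncated at 4 bandwidths so densities have compact support and niche
  membership (z > 0) is well defined. Occupancy z = o/e where e > 0 (else
  0), rescaled to max 1. The availability correction matters because the
  periods compared offer different climates; the uncorrected (raw o) mode is
  available.
* **Schoener's D** is computed on normalized z by default. Exact boundary
  handling: identical grids give exactly 1; grids whose supports do not
  intersect give exactly 0 (including the degenerate corrected-mode case
  where one niche has no occupancy inside its own available environment).
* **Equivalency test.** Pool the two occurrence score sets, reassign at
  random to the original sizes, rebuild both grids against their fixed
  backgrounds, recompute D; `p = (1 + #{D_null ≤ D_obs})/(reps + 1)`,
  one-sided lower (small p: overlap smaller than if the niches were
  interchangeable). Bandwidths are computed once from the observed sets and
  held fixed across replicates, so the null varies only in the assignment.
* **Similarity test.** Replicates replace one side's occurrences with
  random draws from its available environment (the literal "random
  occurrences" null; a translated-cloud `shift` variant is available by
  config); `p = (1 + #{D_null ≥ D_obs})/(reps + 1)` for the default
  "more similar than chance" alternative. The pipeline runs it in both
  directions. The (1+k)/(n+1) convention avoids p = 0 at finite replicates.
* **Niche dynamics.** Within analogous climates (both e > 0 by default; an
  `analog_quantile` can restrict to better-sampled climates), expansion is
  the z-weighted fraction of the paleo niche outside current membership,
  stability its exact complement, and unfilling the mirror fraction of the
  current niche outside paleo membership.
* **Centroid shifts.** Density-weighted mean PC positions of o and of e,
  reported as (occurrence shift, environment shift) vectors.

## Pipeline and determinism

Every stage seed is `(master_seed · 1000003 + crc32(stage_name)) mod 2³¹`,
so a full run is reproducible bit-for-bit from one integer and any stage
can be replayed in isolation. Reports are plain JSON shaped like the two
transferability tables (rows = algorithm × contrast; columns = fit metric,
internal AUC mean/SD, external AUC per scenario) and the overlap table
(one row per scenario pair).

## Problem sizes used in tests

The statistical acceptance suite runs at the study's reference sample sizes
where those carry meaning (404 presences, 100 randomization replicates, 20×
40/60 bootstrap) and scales the incidental dimensions to keep the suite
quick: 60–80 cell grids, 500-cell background samples for the ordination,
200 trials for type-I-error calibration, 200 forest trees inside the
two-condition transferability contrast. These sizes are the package's test
design choices; all are configurable.

## Known limitations

* Raster I/O is the ESRI ASCII grid text dialect only (single band, no
  reprojection); occurrence I/O is CSV.
* The GLM uses per-variable polynomials without interaction terms (the
  standard first-line specification; interactions are easy to add to the
  design builder but not exposed).
* Average-linkage clustering does not guarantee all kept-variable pairs
  satisfy |r| < threshold; violations are detected and logged.
* Kernel occupancy on a finite grid makes D mildly resolution-dependent;
  the doubling-R stability check bounds this at < 0.02 for the default
  settings.
* The equivalency test compares corrected occupancies across *different*
  backgrounds; when the two scenarios share almost no climate, observed D
  approaches 0 and the test loses its interpretation of "identical niches"
  — the analogue-region diagnostics should be consulted first.
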
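# Methods

This note documents the models, conventions and design choices behind
`elevgrad`, in the order the pipeline applies them.

## Domain and range assembly

The spatial unit is the **elevational band**: a discrete stratum of the
gradient sampled by one transect (default: six bands at 1,800–2,800 m in
200-m steps, two slopes). Capture records carry a species code, slope,
elevation, season and count; counts of zero carry no presence. Reported
elevations are snapped to the nearest design band within ±25 m — the
width of the station corridor around a transect line in the survey
design this package models — and anything further off is an input error,
reported with its row number.

A species' **observed range** on a slope is the set of bands with at
least one record; its **interpolated range** fills every band between
its lowest and highest detection (the standard assumption that a species
detected above and below a band is present in it). Range size is the
occupied band count of the interpolated range (an integer 1..m); range
extent in meters is size × band step, a pure rescaling, so the median
split uses band counts. Interpolation is idempotent and can only add
bands, so interpolated richness dominates observed richness bandwise.

Species are partitioned three ways: insectivores vs rodents (from the
traits table), endemic vs non-endemic (traits), and large- vs
small-ranged (range size strictly above the pool median is large; ties
at the median are small). The median split is computed per slope by
default, since each slope's assemblage is analyzed separately; passing a
pooled range collection to `classify_range_size` gives the pooled
variant. Each partition is an exact cover, so group richnesses sum to
total richness at every band — a structural identity the tests enforce.

## The discrete-domain MDE null model

Given the empirical multiset of range sizes {r_i} on an m-band domain,
each simulation draw places every range independently, uniformly over
its m − r + 1 feasible contiguous positions, and tallies per-band
richness. The size multiset is used exactly once per draw — only
midpoints are randomized — so each draw's band total equals Σ r_i
exactly. The prediction is the per-band mean over 5,000 draws with a
95% envelope from the 2.5th/97.5th percentiles; the percentile choice
(over a normal approximation) reflects the small, bounded counts.

The closed-form expectation used for validation is the sum of per-range
coverage probabilities: a range of size r covers band j in
min(j, m−r+1) − max(1, j−r+1) + 1 of its placements, so

    E[S_j] = Σ_i [min(j, m−r_i+1) − max(1, j−r_i+1) + 1] / (m − r_i + 1).

This expectation is symmetric about the domain midpoint, non-decreasing
up to it (the mid-domain hump), and conserves Σ r_i over bands. The
simulation agrees with it to Monte-Carlo error (tested at 3 SE using the
exact per-band binomial variances).

Because richness counts are integers with substantial point masses, the
percentile envelope necessarily over-covers: richness drawn from the
null itself falls inside the 95% CI at ≈97% of band checks (measured
over 500 seeds in the acceptance suite), not exactly 95%. This is a
property of discrete envelopes generally, not of the implementation;
the achievable coverage closest to nominal from above is what the
percentile interval delivers.

The null's explanatory power for an observed richness curve is
quantified by OLS of observed richness on the natural log of the
predicted mean (log of the mean, not mean of logs), reporting ordinary
R² and the two-sided t-test p-value on the slope. The per-band simulated
mean is also the "MDE" predictor handed to the driver models.

## Trend fits and information-theoretic machinery

Polynomial fits (degrees 1–3) regress richness on centered elevation
powers; centering tames the collinearity of raw polynomial bases, and
coefficients are reported on the centered basis. Fits are Gaussian OLS;
the log-likelihood uses the ML residual variance, and

    AICc = −2 logL + 2K + 2K(K+1)/(n − K − 1),

with **K counting every regression coefficient plus the residual
variance** (a straight line has K = 3). This is the dominant convention
in Gaussian-regression information-theoretic practice; it shifts AICc by
a constant within a candidate set and so never changes rankings, but it
does make AICc undefined when n − K − 1 ≤ 0 — on a six-band gradient the
cubic (K = 5) has no AICc and can never be selected. `compare_polynomials`
picks the lowest-AICc degree among those defined, breaking ties toward
the lower degree. Reported R² is ordinary, not adjusted (so it is
non-decreasing in degree, and the AICc winner can differ from the R²
winner). Model significance stars use the F-test.

Akaike weights are exp(−Δ_i/2) normalized over the candidate set;
models with undefined AICc get weight zero. Weights are invariant to
adding a constant to all AICc values.

## Driver selection

**Screen.** All pairwise Pearson correlations among candidate predictors
are computed; within each connected component of the |r| > 0.7 graph,
only the highest-priority predictor is retained. The priority list is an
explicit user choice (default: NDVI first) because the retained
surrogate is an ecological judgement — productivity integrating
temperature and moisture — not something an algorithm should decide.

**Candidate set.** The global model is
`richness ~ slope * (MDE + area + NDVI + PSR)` after the screen: slope
as a 0/1 indicator, the elevational covariates (area, MAT, MAH, NDVI,
PSR) natural-log-transformed, the MDE predictor untransformed (it is
already on the richness scale). All subsets are enumerated under
marginality — an interaction enters only with both parents — giving 97
models for the full five-main-term global (verified against brute-force
subset filtering). Fits are Gaussian with identity link; OLS R² is the
reported fit statistic. A Poisson-log family is available behind a flag
for count-minded users but is not the default. Models whose AICc is
undefined at the design size are excluded with a warning: at n = 12
(6 bands × 2 slopes) the 10-coefficient global model has n − K − 1 = 0,
which is also why saturated interaction models can never win there.

**Selection and averaging.** Best model = lowest AICc (ties: fewer
terms, then lexicographic — ties are measure-zero but tests need
determinism). Model averaging restricts to the smallest best-first
prefix whose cumulative weight reaches 0.95, renormalizes, and reports
per-term importance as the summed weight of containing models; averaged
coefficients use full (zero-substitution) averaging by default with
conditional averaging available. Importance is method-invariant.
Per-term importance within the best model alone is |t|, optionally
rescaled to [0, 100].

**Diagnostics.** VIF_j = 1/(1 − R²_j) from regressing predictor j on
the others (with intercept); values ≥ 5 are flagged, perfect
collinearity reports as infinite. Moran's I of the best model's
residuals uses, by default, row-standardized chain adjacency —
consecutive bands within a slope are neighbors, slopes are disconnected
blocks — which is the minimal neighborhood structure a transect design
supports; inverse-distance weights on coordinates are available behind a
flag. Inference uses the normality-assumption variance with a two-sided
normal p; at n = 12 this test is slightly conservative (≈4% rejection at
nominal 5% on iid residuals) and agrees with a 999-shuffle permutation
p within 0.05, both verified in the tests.

## Synthetic surveys

The generator emulates a standardized two-slope trapping survey:

- **Ranges**: per species, a size drawn from a categorical distribution
  over 1..m, placed either uniformly over feasible positions
  (`mde_null` — exactly the null model's assumption, so empirical
  occupancy converges to the closed form above) or with Gaussian weight
  around an environmental optimum (`environmental`).
- **Detection**: abundance per occupied band and season is
  Poisson(abundance_mean / 2); each individual is detected with
  probability 1 − (1 − q)^T for per-trap-night probability q over T
  trap-nights, i.e. binomial thinning. Defaults (q = 0.001,
  2,200 trap-nights/band across two seasons, 12 individuals per
  occupied band) put overall trap success near 8 captures per 100
  trap-nights, the realistic order for snap/Sherman surveys. With
  q = 1 and high abundance, detection is effectively perfect and range
  assembly recovers the generating ranges exactly (tested).
- **Covariates**: MAT falls with elevation at 0.55 °C/100 m from
  14.5 °C at the base; MAH rises; NDVI = 0.35 − 0.020·MAT + 0.005·MAH;
  PSR = −20 + 4·MAT; Gaussian noise on each. The noise SDs (MAT 0.3 °C,
  MAH 1%, NDVI 0.03, PSR 7 species) were set once so the between-band
  correlation structure matches what mountain surveys report —
  corr(MAT, NDVI) ≈ −0.86, corr(MAH, NDVI) ≈ +0.82,
  corr(MAT, MAH) ≈ −0.90, corr(NDVI, PSR) ≈ −0.64 — in particular so
  that MAT and MAH fall to the |r| > 0.7 screen while PSR survives it.
  Area follows fixed per-slope profiles: one slope tapers with
  elevation, the other bulges at the top (a plateau remnant).
  Covariates are generated on the natural scale; log transforms belong
  to the analysis stage.
- The packaged default is 6 bands × 2 slopes with 27 and 33 species
  (23 shared), matching the assemblage sizes of the reference survey
  design without claiming to reproduce any particular species list.

What the generator does **not** emulate: within-band trap placement,
seasonal phenology, species-specific detectabilities, spatially
autocorrelated covariate noise, or range shapes beyond contiguous
intervals. Tests passing on synthetic surveys therefore certify the
machinery — not any empirical claim about real gradients.

All randomness descends from a single seed via `numpy` `SeedSequence`
stream splitting (separate streams for ranges, counts, covariates and
traits), so identical configurations give byte-identical datasets and
pipeline reruns are bit-identical.

## Problem sizes in the validation suite

The acceptance checks use 5,000 null-model draws (the conventional
envelope size), 500 seeds for envelope-coverage calibration, 200
replicates at 60 band units (2 × 30) for driver recovery with
signal-to-noise 3, and exhaustive placement enumeration for all domain
sizes up to 8 bands. These sizes give Monte-Carlo errors comfortably
below the tolerances tested while keeping the suite quick to run.

## Known limitations

- The Gaussian identity-link family treats richness as continuous; at
  very low counts a Poisson family (provided, non-default) is more
  principled.
- The chain-adjacency Moran weights are one defensible choice among
  several; spatial statistics on n = 12 units have little power either
  way.
- The all-subsets enumeration is exponential in the number of terms; it
  is intended for the handful of predictors that survive a collinearity
  screen, not for wide covariate sets.
- Range interpolation cannot create presences outside the observed
  extremes, so truncated sampling at domain edges biases range sizes
  low; nothing in the package corrects for that.
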
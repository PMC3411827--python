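# Methods

`outwelling` implements the quantitative chain used to test whether estuaries
subsidise adjacent coastal food webs: from stable-isotope endmembers to
feasible dietary contributions, and from community/trait matrices to
distance-gradient inference. This note documents the models, the defaults and
why they are what they are, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## Feasible-solution mixing model

A consumer tissue signature is modelled as a linear mixture of k source
endmembers on two isotope axes:

    δ_j(consumer) = Σ_i p_i · δ_j(source_i),   Σ p_i = 1,  p_i ≥ 0,  j ∈ {13C, 15N}.

With five sources and two isotopes the system is underdetermined, so instead
of solving it the model enumerates *every* proportion vector on the simplex at
a fixed increment and keeps those whose predicted mixture falls within a
mass-balance tolerance of the observation on each axis. The retained set is
summarised per source by 5/25/50/75/95 percentiles (linear interpolation
between order statistics) and min/max. Narrow ranges mean a well-characterised
diet; the distribution of feasible values, not a point estimate, is the result.

Parameters (units, defaults, rationale):

- **increment** (percent, default 1): the grid step on the simplex. At k = 5
  this enumerates C(104, 4) = 4,598,126 vectors; enumeration and the predicted
  signatures are computed once per (source set, increment) and cached, so a
  full 9-site gradient runs in seconds on one CPU.
- **tolerance schedule** (‰, default 0.1 start, 0.1 step, 0.5 ceiling): the
  per-axis mass-balance slack. The search starts tight and escalates only
  until at least one solution exists; `tolerance_used` is reported per site
  because the required slack is itself a diagnostic. Solutions needing more
  than 0.5 ‰ are *indeterminable*.
- **metric** (default per-isotope): feasibility requires |predicted − observed|
  ≤ tol on *each* informative axis; a Euclidean variant is available. A
  mixture with NaN on one axis runs as a single-isotope model.
- **indeterminacy**: flagged when the tolerance ceiling is exhausted, or when
  at least half the sources have feasible ranges spanning from 0 up past 0.9 —
  broad "0% upwards" ranges carry no dietary information even when solutions
  exist. Both thresholds live in `MixingConfig`.
- **consumer aggregation**: individuals are arithmetically averaged per site
  before mixing (the model targets the site mean diet); a per-individual mode
  exists for sensitivity checks.

Proportions are held as integer percentages summing to exactly 100, so no
floating-point drift can leak into feasibility; fractions appear only in
summaries. `sensitivity_resample` propagates endmember standard errors (which
the deterministic model otherwise ignores) by redrawing source means from
Gaussian(mean, SE) and re-running the model under a fixed seed.

## Endmember corrections

Sources are shifted into consumer space by one trophic enrichment factor
(TEF), +0.4 ‰ δ13C and +2.3 ‰ δ15N per trophic level (literature diet-tissue
means for aquatic consumers). Shifting sources up rather than consumers down
is the convention of feasible-solution mixing software; the two are
algebraically identical. The TEF is applied uniformly to all five sources.

Functionally similar producers (saltmarsh + mangrove → fringing vegetation)
are pooled by unweighted means. No standard SE-pooling rule exists, so the
pooled SE is the larger of (a) the mean of member SEs and (b) half the
between-member range divided by √k — deliberately conservative, recorded in
the output, and overridable by supplying a precomputed endmember. Degraded
material is handled the same way: because bacterial decay enriches detritus in
15N (degraded seagrass can exceed δ15N 20 ‰), the endmember is the unweighted
mean of fresh and detrital signatures of the same producer.

Plausibility bounds on ingest (−50 ≤ δ13C ≤ 0, −10 ≤ δ15N ≤ 30 ‰) are advisory
warnings, not failures — enriched detritus legitimately exceeds them.

## Community statistics

**Chao2.** Total richness from incidence across m replicate cores, using the
bias-corrected form S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1)) by default (the
classic Q1²/(2Q2) form is behind a flag and undefined at Q2 = 0, where it
falls back with a warning). Standard errors use the conventional
incidence-based variance formulas with the Q2 = 0 fallback; the formula id is
recorded in the result. Accumulation curves subsample t = 2..m cores without
replacement (seeded), pooling all of a location's cores.

**Bray–Curtis** dissimilarity (via scipy) drives both the location summaries
(between-location dissimilarity on location-pooled vectors; within-location
similarity as 100·(1 − mean pairwise dissimilarity among site-pooled vectors))
and the distance matrices for the inference stage.

**Biological traits.** Community function is profiled by the linear expansion
`site × trait = counts @ scores` over a 32-trait table spanning living
position, sediment topography, particle movement, motility, feeding, body
size, shape and hardness. Fuzzy-coded (fractional) scores are supported;
binary tables are a special case. Because the expansion is linear it commutes
with pooling samples — a property the tests exploit.

## Distance-based linear models

Squared distances are Gower-centred (G = C(−½D∘D)C) and covariate designs are
column-centred, so the explained variation tr(HGH)/tr(G), the pseudo-F

    F = [tr(HGH)/m] / [tr((I−H)G(I−H)) / (n−m−1)],

adjusted R² = 1 − (1−R²)(n−1)/(n−m−1), and AIC = n·ln(SS_res/n) + 2(m+1) all
operate on the distance-variation partition. AIC conventions for
distance-based models differ between packages; the form used is echoed in the
result metadata.

Significance comes from unrestricted permutation of the sample labels of the
distance matrix. With n ≤ 9 sites all n! ≤ 362,880 permutations are
enumerated exactly (p = #{F* ≥ F}/n!); passing an explicit permutation count
switches to Monte-Carlo with p = (#{F* ≥ F} + 1)/(B + 1). Environmental
covariates are z-scored (optionally within location) before modelling.

Model search is backwards elimination: repeatedly drop the covariate whose
removal most improves the criterion (AIC or adjusted R²) until no removal
improves it. A small-n caveat: with 9 sites the AIC penalty (2 per parameter)
is weaker than the chance fit of a random covariate once residual df ≤ 2, so
AIC tends to retain saturated models; adjusted R² prunes more aggressively and
is the better default when n is this small. Both are reported.

Light gradient statistics — one-way ANOVA, Tukey HSD (scipy's studentized
range), Bonferroni-adjusted pairwise categorical contrasts, and linear or
exponential-decay (y = a·e^(−bx), fitted by least squares from a log-linear
start) distance regressions — describe single covariates along the gradient.
The categorical family uses a Gaussian one-way model; pairwise contrasts are
Welch t-tests with Bonferroni correction.

Ordination plots use principal coordinates of the Gower-centred matrix
(eigendecomposition, negative eigenvalues clipped at zero, sign fixed by the
largest loading).

## Synthetic scenario

The generator emulates the full study design so every stage is testable
without field data: two locations × 9 subtidal sites at ~200–300 m spacing
(ranks 1–9 from the estuary mouth, also emitted in metres), 15 cores and 10
quadrats per site, 3–5 consumers per site, five endmembers per estuary.

- **Endmember means** default to the field values for these estuaries
  (estuarine SPOM (−22.4, 7.7) / (−22.9, 3.4), marine SPOM (−19.6, 4.3/4.0),
  seagrass-detritus blended (−12.1, 15.8) where degradation applies and
  (−10, 7) fresh-corrected otherwise, microphytobenthos (−13, 5.8), fringing
  vegetation (−27, 4)). Endmember SEs (0.3 ‰) are placeholders — replicate-
  level field values are unavailable — and are flagged as such in the config.
- **True mixtures**: the estuarine-SPOM share decays linearly along the
  gradient (0.6 → 0.4 at one location, 0.3 → 0.1 at the other); the remaining
  mass is split among the other sources in fixed location-specific ratios
  (SPOM-dominated at one location, seagrass/fringing-weighted at the other).
  Consumer noise is Gaussian, sd 0.3 ‰ per isotope.
- **Communities**: both locations draw their pools (130 vs 90 taxa) from one
  shared regional pool of 150, with lognormal (σ = 1.5) rank abundances,
  lognormal location modifiers (σ = 0.8), per-taxon responses to the
  standardized distance rank and to log Dosinia density (half the taxa
  respond; coefficients N(0, 0.5) and N(0, 0.35)), and negative-binomial core
  counts (dispersion 2, ≈45 individuals per core) — standard benthic-community
  assumptions, recorded in the truth sidecar. `gradient_effect=0` produces an
  exact null.
- **Environment**: organic content and chlorophyll a decline along the
  gradient at one location only; Dosinia density is high near the mouth and
  decaying at the other location and flat elsewhere; grain-size fractions,
  carbonate (with one anomalously high far site) and phaeophytin are generated
  with plausible noise.

What the generator does *not* emulate: hydrodynamic transport, tidal
advection, tissue turnover, spatial autocorrelation between neighbouring
sites, taxonomic identification error, and the real (unpublished) trait
codings — its 32-trait table is fabricated within the named categories.
Passing tests therefore demonstrate that the estimators and the search are
correct and that the pipeline recovers the structure it assumes, not that the
field conclusions are reproduced.

## Numerical and reproducibility choices

- Enumeration and predicted-signature caches are keyed by (source means,
  increment); memory is bounded by small LRU caches (the k = 5, 1% grid is
  ~46 MB as int16, predictions ~74 MB as float64).
- Percentile method: linear interpolation; recorded in output metadata.
- Feasibility comparisons use ≤ with exact float semantics; predictions are
  computed in float64 so boundary membership matches an independent
  double-precision oracle.
- All randomness flows through `numpy.random.default_rng` seeded from a single
  run seed; manifests exclude wall-clock timestamps so identical runs produce
  byte-identical outputs, and every CSV is written with a fixed float format
  and line terminator.
- Degenerate inputs: mixtures outside the polygon return empty indeterminable
  sets (no exception); identical sources trigger the breadth flag; constant
  responses give R² = 0 with p = 1; zero-variance ANOVA groups give F = 0,
  p = 1.

## Known limitations

- Medians of an underdetermined feasible set shrink toward the interior of
  the simplex; with five sources and two isotopes a true 0.30 contribution can
  report a median near 0.2 while remaining inside the feasible range. Ranges,
  not medians, are the primary output.
- The distance-based AIC is anti-conservative at n = 9 (see above).
- Between-location community contrasts depend on the regional-pool overlap
  parameter, which has no field-measured value here.
- The exponential-decay family assumes positive y; the categorical family
  assumes Gaussian errors.
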
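# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
landscapes do and do not establish about real data.

## Data model and filtering

Trees from both eras are collapsed onto 24 broad taxon groups (ashes,
basswood, beech, birches, blackgum, cedar, cherries, chestnut, cypress,
elms, fir, hemlock, hickories, hornbeam, magnolias, maple, oak, pines,
poplars, spruces, sycamore, tamarack, tulip, walnuts), because colonial
surveyors rarely resolved species within a genus. Name matching is case-
and whitespace-insensitive; unmatched names are flagged `UNBINNED`,
excluded from compositions, and counted in the logs — never dropped
silently.

Modern-inventory filters: trees below 12.5 cm dbh are excluded (closed
bound — a tree at exactly 12.5 cm is retained, so the rule is testable
exactly); plots must be condition-class `Forest` and hold at least 10
qualifying trees; towns must retain at least 2 plots. The filter is
idempotent by construction.

A town's composition in either era is the **pooled stem proportion** over
its retained trees. Pooling (rather than averaging per-plot proportions)
keeps the eras symmetric, since witness trees carry no plot structure;
per-plot compositions appear only inside the adequacy bootstrap. Rows of a
composition table always sum to 1 within 1e-9.

Geometry: town centroids come from the polygon centroid, areas from an
equal-area local projection (cos-latitude scaling + shoelace), and all
inter-town distances are great-circle (haversine) km — over an ~8° span of
latitude, planar approximations drift.

## Sampling adequacy

Whether a town's trees adequately sample its compositional diversity is
decided per ecoregion:

1. Within each ecoregion take the most densely sampled towns: ≥5 plots
   (inventory path) or ≥100 witness trees (witness path), and density at or
   above the within-ecoregion upper-tercile boundary (closed bound). The
   tercile is computed within ecoregion, consistent with the ecoregion
   stratification of the rest of the procedure.
2. For each such town, 100 bootstrap sets: in each set, for n = 1..N units,
   one sample of n units with replacement; similarity = 1 − Sørensen
   between the pooled sample and the full town. Witness trees are first
   partitioned into random bins of 20 (re-randomized each set; leftovers
   beyond a multiple of 20 dropped within the set). "Similarity" here is
   1 − the Sørensen distance defined below.
3. Fit the through-origin Michaelis–Menten curve y = S_max·n/(k + n) to
   each set by least squares (scipy `curve_fit`, S_max bounded in (0, 1]).
   The sample size reaching a proportion q of S_max is n = k·q/(1−q) — at
   the default q = 0.9, exactly 9k, which serves as an internal analytic
   cross-check on every converged fit. Non-converging sets are logged and
   skipped; towns with no converging set are excluded from averaging.
4. Per town: mean over sets of (9k / town area). Per ecoregion: mean over
   eligible towns, separately for plots and witness trees.

A town enters the analysis iff its witness-tree density **and** its plot
density meet their ecoregion thresholds (closed bounds).

## Change statistics

The abundance-based Sørensen distance between abundance vectors x, y is
`Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; on relative abundances the denominator is 2, making
it half the L1 distance — 0 for identical composition, 1 for disjoint
support. It is a semimetric (no triangle inequality is asserted or used).

Significance conventions, used everywhere:

* permutation/Monte Carlo p-values are `(1 + #{null ≥ observed}) / (1 + n_rand)`,
  so p is never exactly zero;
* tests are two-sided via absolute-value statistics;
* the paired Monte Carlo test uses |mean(pre − mod)| with a sign-flip null
  (each pair's labels swapped independently with probability ½, 10,000
  randomizations by default). The statistic is the plain mean difference
  rather than a t-like ratio; this is documented as a choice, and its
  type-I calibration is verified by simulation in the test suite.
* group comparisons shuffle pooled values between the two groups.

No multiple-testing correction is applied across the 24 taxa of the
abundance-change table; the per-taxon p-values are reported raw.

β-diversity is each town's mean Sørensen dissimilarity to all other towns
in scope, per era; eras are compared by a permutation test on the per-town
means. A pre→modern drop indicates biotic homogenization.

## Spatial statistics

* **Moran's I correlogram** of a per-town scalar: binary weights per
  half-open 15-km distance class `[lo, hi)`, I = (n/W)·Σwᵢⱼzᵢzⱼ/Σzᵢ², with
  permutation p-values two-sided around the randomization expectation
  −1/(n−1). By default classes run to half the maximum inter-town distance
  (an edge-effect guard); the class width is configurable (the method is
  conventionally reported with 15- or 20-km classes; 15 is the default
  here).
* **Mantel test**: Pearson correlation of upper triangles; null by jointly
  permuting rows+columns of one matrix; two-sided.
* **Mantel correlogram**: per class, the second matrix is the binary
  within-class indicator and the correlation is **negated**, so positive
  r_M means towns in that class are more similar than expected. Degenerate
  classes (no pairs, or all pairs) are reported as missing. Significance
  uses a plain Bonferroni-corrected α across evaluated classes — plain
  rather than the progressive (Holm-style) variant, matching the stated
  analysis convention this package follows.
* **Environment Mantel table**: environmental distance is the absolute
  difference of the scalar covariate; r_M and p per covariate
  (temperature/GDD, precipitation, elevation, soil sand) per era.

## Ordination

NMDS on Sørensen distances of Wisconsin-standardized (columns by maxima,
then rows by sums) pooled pre+modern compositions. The embedding is SMACOF
with isotonic regression (scikit-learn, ties averaged — the primary
approach), best of 50 random starts; goodness of fit is Kruskal stress-1,
recomputed from the final configuration so values are comparable across k.
Coordinates are centered and PC-rotated so axis 1 carries maximal variance.
Half-change scaling is omitted as presentation-only; PC rotation is kept
because the era-separation readout depends on axis identity.

The era-separation readout picks the axis maximizing the standardized
between-era mean difference (rather than asserting "axis 2" a priori),
fixes its sign so the pre-colonial mean is negative, and reports the
fraction of pre-colonial scores below zero and modern scores above zero.

Environmental vectors are least-squares regressions of each covariate on
the axis scores (unit direction cosines, R², permutation p). The SMACOF
convergence tolerance is 1e-9 on the relative stress change with up to 500
iterations; looser tolerances leave visible stress floors (~2e-3) even on
exactly embeddable configurations.

## Conditional-inference tree

A deliberately simplified conditional-inference tree, not the full
quadratic-form framework: at each node, every predictor's association with
the response is measured by |Pearson r| with a Monte Carlo permutation
p-value (9,999 permutations, shared across predictors), Bonferroni-adjusted
across predictors. The node becomes a leaf if the best adjusted p is not
below α = 0.05 or fewer than 2·min_node rows remain; otherwise the winning
predictor is split at the cutpoint maximizing the standardized two-sample
mean difference, subject to min_node = 20 on both sides, and the children
recurse. Thresholds are midpoints between adjacent observed values; rows at
a threshold route left. min_node and the permutation count are package
defaults (chosen to keep ~5-partition trees reachable at ~700 rows);
α → 0 provably yields a single leaf, and the pure-noise false-split rate is
verified by simulation.

## Synthetic landscapes

The generator builds the statistical structure the analysis assumes, with
ground truth exposed for every stage:

* towns tile a lon/lat grid (default 12×10 towns of ~0.09°, ≈80 km² —
  about the size of a 6-mile-square colonial town); four latitudinal
  ecoregion bands;
* growing degree days fall linearly from 4400 (south) to 2600 (north) plus
  N(0, 60) noise; each taxon has a Gaussian niche
  `a_t ∝ peak_t·exp(−(GDD−opt_t)²/2w_t²)` with optima ordering taxa from
  boreal (spruce/fir) to warm-temperate (oak/hickory/chestnut) and peaks
  tuned so the regional pre-colonial means echo a beech/oak-dominated
  northeastern forest;
* peak agricultural clearing rises with warmth (base 0.12 + 0.55·GDD-norm
  + N(0, 0.10), clipped to [0.01, 0.95]), so land-use history is
  spatially structured — which is what makes the change surface spatially
  clustered and the regression tree's task non-trivial;
* the modern era multiplies each taxon by a rule `max(0, base +
  slope·agriculture)` and renormalizes: chestnut ×0 everywhere; beech,
  hemlock and oak decline with clearing; maple, cherries, poplars, birches
  and fir rise. The default rules reproduce the qualitative four-century
  pattern (maple roughly tripling, beech halving, chestnut extirpated,
  modest homogenization, weakened GDD coupling);
* witness trees are multinomial draws from the town profile (negative
  binomial counts, mean 250/town); the inventory draws Poisson(4.3) plots
  per town (min 2) of Poisson(36) trees, each plot's profile drawn from
  Dirichlet(θ·profile) with θ = 60 to emulate within-town clustering of a
  plot-based design; diameters are 12.5 + Gamma(2, 8) cm so the size filter
  passes by construction unless `frac_small_trees`/`nonforest_prob` are
  raised. Per-town scale matches the study design this emulates
  (≈250 witness trees, ≈4.3 plots, ≈150 inventory trees per ~100 km² town).

Everything is deterministic under the config seed (byte-identical output
files).

**What passing tests do not show about real data**: the generator has no
surveyor bias (species preferences, corner-placement effects), no tree
sizes below the retention threshold by default, no succession dynamics, no
species invasions, and its era shift is a per-taxon multiplier — real
change processes are not multiplicative in town composition. Tests against
it establish that the statistics recover planted structure, not that the
historical inferences are correct.

## Problem sizes and numerical choices

* Default analysis scale is the 120-town landscape; the acceptance script
  runs the full pipeline at that scale (~2 min) with the standard
  parameters (100 bootstrap sets, 10,000 Monte Carlo randomizations, 999
  permutations, 50 NMDS starts, 9,999 tree permutations) and a two-point
  (k = 1, 2) stress scree; the k = 1..4 scree lives in the ordination
  driver.
* Unit tests use reduced replication; the acceptance test suite verifies
  the statistics against brute-force double-loop oracles to 1e-12 and the
  permutation tests' type-I error at α = 0.05 over 1000 null datasets.
* Degenerate inputs: constant values (Moran), zero-variance triangles
  (Mantel), all-equal dissimilarities (NMDS), constant covariates (envfit)
  and constant responses (tree nodes) are rejected or flagged rather than
  returning NaNs.

## Known limitations

* The Michaelis–Menten fit is through the origin; towns whose similarity
  curves decrease (possible at very low unit counts) are excluded from
  threshold averaging rather than fit with an intercept.
* The Mantel correlogram's Bonferroni correction is plain, not
  progressive; with many classes it is conservative at long lags.
* The regression tree's linear statistic only detects monotone
  associations at the split-selection stage; a predictor with a purely
  non-monotone effect can be missed.
* The NMDS era-separation fraction depends on the fitted configuration;
  different seeds can rotate which axis separates the eras (the readout
  chooses the axis from the data for exactly this reason).
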
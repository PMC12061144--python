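# Methods

This note documents the models and procedures the package implements, the
defaults it ships with and why, and what its synthetic validation does and
does not demonstrate.

## Spatial substrate

All rasters are geographic WGS84 lon/lat grids with square cells, row 0
northmost, pixel-is-area, cells half-open `[west, east) × (south, north]`
(matching the dominant GeoTIFF convention for climate rasters). GeoTIFF
read/write is implemented directly on TIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) via `tifffile`; files in the
pixel-is-point convention are shifted by half a cell on read, and projected
CRSs are rejected with an instruction to reproject. On alignment, continuous
(climate, topography) layers are resampled bilinearly and fraction/categorical
(land-use) layers by nearest neighbour — nearest preserves the [0, 1] bounds
of fraction layers exactly, which bilinear would only do approximately. Any
nodata touching an interpolation footprint propagates to nodata.

Cell areas are spherical: A = R²·Δλ·(sin φ_top − sin φ_bottom) with the IUGG
mean radius R = 6371.0088 km. The ellipsoidal correction is below 0.3 %,
far below the precision at which range areas are compared; the sphere keeps
the formula exactly testable against closed forms (a global grid sums to
4πR² to < 0.01 %).

## Occurrence thinning

Records of one population are rarefied so that all retained pairs are at
least `radius_km` (default 5 km) apart by haversine distance. The algorithm
is greedy maximum-neighbour deletion: repeatedly remove the record with the
most within-radius neighbours, ties broken uniformly at random from the
seed. Greedy deletion alone can strand records whose blockers were
themselves deleted later, so a seeded re-add pass runs to a fixpoint; the
result is maximal — no removed record can be re-added without violating the
constraint — which is exactly the property the tests verify with an
all-pairs oracle. Populations are thinned independently, since each
population is modelled separately and cross-population proximity carries no
bias for a per-population model.

## Predictor importance and selection

Importance is prediction-permutation importance on a preliminary model
fitted to all predictors: `importance(v) = mean over replicates of
1 − max(0, r(p, p_with_v_permuted))`, where `p` are the model's predictions.
A variable the model ignores scores exactly 0; a variable the predictions
copy scores near 1. A leave-one-variable-out refit delta-AUC variant
(`loo_auc_importance`) is available for callers who want importance tied to
held-out discrimination; the permutation form is the default because it
needs no refitting and is the convention of ensemble-SDM platforms.

Collinearity pruning: among surviving predictors, find the pair with the
largest |Pearson r|; if it exceeds the threshold (default 0.7), remove its
lower-importance member (importance ties drop the lexicographically later
name); recompute and repeat. Attacking the worst pair first makes the
order-ambiguous loop deterministic, and the retained set provably contains
no pair above the threshold (asserted post-hoc on every run). Importance is
computed once on the preliminary all-predictor model, not refitted between
removals, mirroring the two-stage preliminary-model → selection → final-model
design. Exact-constant columns are treated as uncorrelated with a warning.

## Ensemble SDM

Presence-only data are complemented with pseudo-absences sampled uniformly
without replacement from valid cells not containing an occurrence: 1000 of
them, or as many as there are occurrences when fewer than 1000. Validation
uses repeated random stratified 70/30 train/test partitions (default 5
repeats — read as five independent random splits, not 5-fold). Each
(algorithm, split) candidate is evaluated on its held-out fold; candidates
with TSS < 0.7 or AUC < 0.8 are excluded, and the ensemble score is the
unweighted mean of the survivors (a TSS-weighted mean is available but off
by default, since gating — not weighting — is the stated protocol).
Presences and pseudo-absences are equally weighted in fitting.

AUC uses the rank (Mann-Whitney) formulation with ties counted ½. The MSS
threshold scans candidate thresholds (midpoints of consecutive sorted unique
scores, plus both extremes) for the maximum of sensitivity + specificity
under the rule score ≥ t ⇒ presence; the objective is compared on exact
integer counts so ties are genuine, and ties break toward the lowest
threshold (the more inclusive range). TSS = sensitivity + specificity − 1 at
that threshold. The ensemble's own MSS threshold is calibrated on the pooled
presence/pseudo-absence training set and is the threshold used to binarize
projections.

Seven algorithm families are registered, all on scikit-learn learners:

| id | implementation |
| --- | --- |
| `ann` | multilayer perceptron (scaled, one hidden layer of 16) |
| `cta` | classification tree (depth ≤ 8, ≥ 10 per leaf) |
| `fda` | flexible discriminant: spline basis + LDA |
| `maxent` | regularized logistic regression (the exponential-family equivalent of a maximum-entropy model) |
| `rf` | random forest (100 trees) |
| `gam` | spline basis + logistic link |
| `gbm` | gradient boosting (100 stumps of depth 3) |

Bit-exact parity with any existing SDM platform's learners is a non-goal;
the committee-plus-gates structure is the point. The pipeline default is
`maxent + rf + gbm`: enough member averaging to stabilize the ensemble MSS
threshold at desk scale. All randomness (splits, member fitting,
pseudo-absences) flows from one master seed via spawned per-stage seeds, so
a run is bitwise reproducible.

## Null models

Per replicate (default 10): draw virtual presence records — 70 % of the
actual occurrence count, rounded half away from zero — uniformly from valid
cells; fit the same algorithm specs on virtual presences plus fresh
pseudo-absences; evaluate against a freshly drawn held-out 30 % of the real
records (plus their own pseudo-absences). The held-out 30 % is redrawn per
replicate (the alternative — one fixed holdout — would make replicate skill
estimates even more correlated). Real-vs-null comparison is a one-sided
Welch t-test per metric (real > null), with the Welch–Satterthwaite degrees
of freedom; two zero-variance equal-mean samples give p = 1 by convention.
One caveat the calibration tests respect: null replicates sharing one real
occurrence sample are positively correlated, so calibration checks block
over independent real-record draws before averaging.

## Range-shift decomposition

Binary maps come from `suitability ≥ threshold` on valid cells; nodata cells
are absent and counted as excluded. For an introduced/native pair on the
same grid: expansion = introduced ∧ ¬native, stabilization = both,
unfilling = native ∧ ¬introduced, with areas summed from the per-cell area
map. Cells nodata in *either* map are excluded from all three components —
asymmetric inclusion would break the exact swap symmetry
(expansion ↔ unfilling under argument exchange) that the tests enforce.
Conservation (the three components tile the union exactly) and the identity
of IRS with the area-weighted Sørensen coincidence are exact invariants.

Both RR directions (IR/NR and NR/IR) and both IRS variants (2RS/(IR+NR) and
RS/(IR+NR)) are always computed and labelled, because both conventions
circulate in the range-shift literature and reported values do not always
match the formula printed beside them; nothing downstream silently picks
one. Areas are carried in km² and echoed in units of 10⁴ km² with two
decimals in reports.

## The virtual-species generator

Each synthetic region ("continent") gets one grid per predictor:
`a·(lat/15) + b·((lon − lon_west)/30) + amplitude·smoothed-noise`, where the
noise is a moving-average (radius `noise_smoothing` cells) of white noise —
dependency-free and exactly reproducible — and land-use layers are squashed
to [0, 1] by a logistic. Two deliberate design choices make *transfer*
meaningful:

* the gradient slopes (a, b) derive from a CRC32 hash of the predictor
  *name*, never from the region, so "annual mean temperature" responds to
  latitude identically on every continent and only the noise ("weather")
  differs;
* the longitudinal term is continentality (distance from the region's west
  edge), not absolute longitude, so predictor distributions are comparable
  across continents.

Orientations diversify the roster — temperature/precipitation layers are
strongly latitudinal (and hence strongly mutually collinear, as bioclim
variables are in reality), land-use longitudinal, topography mixed — so
collinearity pruning has real work to do.

True suitability is `logistic(intercept + Σ coef · standardized predictor)`;
standardization constants default to the stack's own but the scenario
evaluates each species with its *home-region* constants everywhere, so the
same niche is expressed in the same raw units on every region. The true
range is `suitability ≥ occupancy_threshold` (default 0.5). Occurrences are
drawn cell-wise proportional to suitability (optionally times a longitudinal
bias gradient raised to `sampling_bias_strength`), without replacement while
enough habitable cells remain, with uniform jitter inside the drawn cell.

### Default scenario

Two 30°×30° regions at 0.3° cells (100×100), latitudes 25–55°: a source
"palearctic" and a target "nearctic". Two species share the dominant thermal
coefficient (bio1) and diverge in their secondary term and baseline
prevalence: a widespread `native` (bio1 14, bio12 2.5, intercept −18.5,
~18 % of cells suitable) sampled on the source region, and a rarer
`introduced` (bio1 16, bio4 −2.5, intercept −17.5, ~12 %) sampled on the
target, 500 occurrences each. The parameters follow three constraints any
recoverable design must satisfy:

1. with uniform pseudo-absences the achievable TSS is roughly
   1 − (fraction of unoccupied cells inside the range), so TSS ≥ 0.7 gates
   demand modest prevalence and steep (near-threshold) suitability;
2. without-replacement occurrence sampling spills presences outside ranges
   not comfortably larger than the sample size, so each true range holds at
   least about twice `n_occurrences` cells;
3. a range truncated at the region edge biases the MSS-binarized range
   badly, so both range boundaries lie well inside the region.

Grid sizes are a desk-scale choice; the generator itself defaults to 2.5
arc-minute cells for realism when regions are small.

### What the synthetic validation does and does not show

Passing recovery (Jaccard ≥ 0.5 against true ranges; RR/IRS within ±25 % of
truth) demonstrates that the pipeline's stages compose correctly and that
the estimators are consistent when the data-generating process is inside the
model family (logistic-linear niches, unbiased sampling, stationary
gradients). Real data violate all of these: niches are not logistic-linear,
GBIF sampling is strongly biased and spatially clustered beyond what the
one-knob bias gradient emulates, predictors are interpolated products with
their own error, and transfer between continents involves genuinely novel
environments (extrapolation) that the synthetic continents, sharing their
gradient structure by construction, do not produce. The synthetic results
therefore validate the software, not the ecology.

## Numerical choices

* MSS objective compared on integer counts (`tp·n_neg + tn·n_pos`) — exact
  tie handling; ties to the lowest threshold.
* Constancy checks use `ptp == 0`, not `std == 0` (the standard deviation of
  a constant float array is not exactly zero).
* Permutation-importance scores below 1e-10 snap to 0 so ignored variables
  score exactly 0.
* 70 % record counts round half away from zero (446 from 637), and the
  convention is in the config so it is visible in reports.
* Welch df computed explicitly; both-samples-constant handled by convention
  (p = 1 if means equal, else p = 0).
* Empty ranges make RR undefined (NaN) in a decomposition result; the
  standalone `range_ratio` raises instead, since a caller asking for the
  ratio of an empty range has made an error.

## Limitations

* Geographic CRSs only; no projected grids, no vector I/O, no out-of-core
  tiling.
* No environmental-space analyses (Schoener's D and relatives), no
  dispersal or population dynamics, no future-climate projection.
* The null models randomize occurrence positions only; spatially structured
  nulls are out of scope.
* Thinning is O(n²) per population — fine for 10⁴ records, not for 10⁶.
* The seven algorithm slots are faithful in family, not in implementation,
  to any particular SDM platform.
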
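# Methods

## Overview

riskpipe estimates where a forest pest could establish (climate
suitability), where it is likely to arrive (introduction likelihood),
and what an establishment would cost at the administrative level
(economic concentration of the host crop). The three strands are:

1. presence-only suitability modelling with a minimal MaxEnt core and
   its standard tuning/evaluation protocol;
2. an invasion-risk surface as the product of suitability and a
   normalized introduction-likelihood layer;
3. a municipality risk matrix crossing mean suitability with the
   normalized Concentration Index (nCI) of the host product.

Everything operates on in-memory numpy rasters tagged with a north-up
geotransform; text formats (ESRI ASCII grid, CSV, GeoJSON) are the
exchange surface.

## MaxEnt core

### Model

Over a finite set of background cells B with feature vectors f(x) ∈
[0,1]^d, the model is the Gibbs distribution q(x) = exp(λ·f(x))/Z(λ),
Z = Σ_B exp(λ·f(b)). With m presence records the fit maximizes

    J(λ) = Σ_presence λ·f(x) − m·ln Z(λ) − Σ_j β_j |λ_j|.

This is the standard presence-background maximum-entropy estimator: the
L1 penalty makes the solution sparse, with k = #{j : λ_j ≠ 0} serving
as the parameter count in AICc.

Assumptions worth keeping in mind: presences are treated as an
unbiased sample of the occupied environment within the background
region; the background characterizes what is *available*, not
absences; and suitability is an equilibrium description (no dispersal
or biotic interactions).

### Features

- linear, quadratic, and pairwise-product features are raw transforms
  min-max scaled to [0,1] on the background sample and clamped to
  [0,1] at prediction time;
- hinge features are forward/reverse ramps max(0, ±(x−t))/span at
  `n_hinge_knots` (default 20) evenly spaced quantile knots strictly
  inside each variable's background range.

Per-feature penalties are β_j = rm · β_class(m) · s_j/√m where s_j is
the feature's background standard deviation, rm the user's
regularization multiplier, and β_class interpolates (1.0, 0.2, 0.05)
at presence counts (10, 30, 100) for linear/quadratic/product features
(constant 0.5 for hinge). These follow the conventional presence-count
schedules; they are configuration, not estimates.

Presence cells are appended to the background for Z (the usual
convention, so the presence environment is always "available").

### Optimization

Proximal gradient ascent with soft-thresholding for the L1 term,
FISTA-type momentum, and a monotone restart: an extrapolated step that
would lower the penalized objective is discarded for a plain proximal
step whose backtracking (majorization) condition guarantees ascent.
The iteration log therefore never decreases — a tested invariant.
Termination: objective improvement < 1e-7 or 5000 iterations;
non-convergence returns the best iterate with a warning. The default
tolerance targets map-making; analytic comparisons of λ itself (e.g.
the closed-form single-binary-feature solution) should pass `tol=1e-12`
because the objective is very flat near the optimum.

### Outputs

`raw` = exp(λ·f − ln Z) sums to one over the training background;
`cloglog` = 1 − exp(−e^H·raw) with H the entropy of the fitted
background distribution, mapping to [0,1] for maps. Both are rank
-equivalent; AICc uses raw scores renormalized over the prediction
grid.

## Occurrence handling

- Exact duplicate coordinates are dropped (keep-first) before
  thinning.
- Thinning enforces a minimum pairwise haversine distance (Earth
  radius 6371 km) between retained records; default 20 km. The
  retained set should be as large as possible: for ≤ 25 records the
  exact maximum independent set of the conflict graph is computed
  (branch-and-bound maximum clique on the complement graph); larger
  sets use the replicated greedy heuristic (repeatedly drop a record
  with most conflicts, random tie-break; best of `n_replicates` runs,
  default 10). Exactness at small n makes the procedure's optimality
  testable; at realistic sizes the heuristic matches standard
  practice. Input/output counts and per-replicate retention are
  returned in a report.
- The training background is the union of climate zones containing at
  least one occurrence, intersected with valid predictor cells;
  background points are drawn uniformly without replacement (default
  10,000, capped with a warning).

## Predictor filtering

VIF_v = 1/(1 − R²_v) from OLS of predictor v on the others (computed
with statsmodels on a fixed random sample of ≤ 10,000 cells; perfect
collinearity yields +inf, not an exception). Iterative elimination
removes the largest-VIF non-forced variable while it exceeds the
threshold (default 10); ties break by band order. Forced variables are
never removed; forcing everything skips filtering with a warning.

## Evaluation protocol

- **Tuning grid**: multipliers 0.5–5.0 (step 0.5) × class sets L, Q,
  LQ, LQH, LQHP = 50 candidates. Each candidate is fit once on the
  full thinned record set; AICc (2k − 2lnL + 2k(k+1)/(n−k−1), lnL on
  grid-renormalized raw scores, undefined when k = 0 or k ≥ n−1) picks
  the winner, ties broken by smaller k then smaller multiplier.
  AUC/CBI train and test values score that same model on a
  reproducible 75/25 record split; candidates are not refit per
  partition, which keeps the grid cheap at the cost of slightly
  optimistic test values (the relative ranking, which is what tuning
  uses, is unaffected).
- **AUC**: Mann–Whitney rank statistic with ties counted half.
- **Null-model test**: n_null (default 100) refits with the selected
  settings to pseudo-occurrence sets drawn uniformly from the
  background mask; both empirical and null AUCs are
  all-presences-vs-background from full-set fits so the comparison is
  like-for-like. Significance requires the empirical AUC to strictly
  exceed at least ⌈0.95·n_null⌉ null values — ties count against
  (conservative). Calibration on no-niche species is tested at ~7.5%
  empirical type-I over 40 repeats.
- **Continuous Boyce Index**: 101 overlapping windows of width 10% on
  the landscape's empirical-CDF (rank) scale; P/E = presence share /
  landscape share per window, windows with E = 0 dropped; CBI is the
  Spearman correlation of window midpoint vs P/E. Windowing on the
  rank scale (rather than the raw score range) makes the index exactly
  invariant under strictly increasing transforms of the scores, which
  is the property that justifies comparing CBI across output scales;
  window count and width keep their conventional values. Fewer than 3
  usable windows yields NaN.

## Risk mapping

- Introduction surfaces are min-max normalized; constant surfaces
  become zeros with a warning.
- Invasion risk is the cellwise product after bilinear resampling of
  the introduction layer onto the suitability grid (continuous field);
  nodata propagates.
- Jenks natural breaks is the exact Fisher dynamic program minimizing
  total within-class SSD; grids larger than 10,000 valid cells are
  subsampled uniformly (seed logged) since the DP is O(k·n²). Breaks
  are the largest value of each class; assignment is right-closed
  (value equal to a break falls in the lower class) with the first
  interval left-closed.
- All polygon↔raster membership uses the cell-center rule, in both
  `zonal_mean` and `plantation_overlap`; plantation polygons are
  unioned before rasterization so overlapping or split geometries
  count each cell once, and overlap fractions are reported per class
  (summing to 1) without equal-area reprojection.

## Economic indices

LQ, HHI, RP as defined in the README; all are scale-free in the
currency unit (tested to 1e-12). The nCI combines the z-standardized
columns (population std) with weights θ from the eigen-decomposition
of their 3×3 correlation matrix: θ_m ∝ Σ_k (λ_k/Σλ)·|v_mk|/Σ|v_·k|,
renormalized to sum 1. Absolute loadings remove eigenvector sign
ambiguity; standardizing before both the PCA and the weighted sum
follows the usual construction of composite regional indices. The risk
matrix classifies mean municipal suitability and nCI into five Jenks
classes each (computed on standardized nCI, consistent with the index
construction); the mean of the two class indices maps to four levels
via right-closed intervals (≤1.5 very low, ≤2.0 low, ≤3.0 moderate,
≤5.0 high), so a (1,2) pair with mean 1.5 is "very low".
Municipalities with zero product value are retained and simply land in
the lowest classes.

## Synthetic world

The generator supplies study-shaped inputs with known ground truth:

- **Climate fields**: Gaussian-smoothed white noise (correlation
  length = `smoothness` cells, wrap-around boundary), standardized per
  band; designed collinear pairs are built as ρ·base + √(1−ρ²)·noise
  from smoothed fields, achieving sample |r| within ±0.05 of target.
- **Virtual species**: occurrence probability is an axis-aligned
  Gaussian in predictor space (known optimum/tolerance, peak
  `max_prob`), so the true suitability ranking is available cell by
  cell. Presences are sampled at cell centers without replacement,
  probability ∝ surface value.
- **Zones**: k-means clusters of standardized predictor vectors,
  relabelled deterministically — the role of discrete climate zones
  for background delimitation.
- **Production table**: a Dirichlet split in which `n_concentrated`
  municipalities hold `concentration_share` of national product value;
  total forestry value adds an independent gamma-distributed
  remainder, guaranteeing VP_ij ≤ VP_j and exact national totals.
- **Ancillary layers**: a smooth introduction surface on an arbitrary
  scale (so normalization is exercised), and cell-aligned rectangular
  municipality tilings and plantation rectangles whose exact cell
  memberships are returned for oracle tests.

What the generator does *not* emulate: sampling bias and coordinate
error in occurrence records, non-Gaussian or interacting niche
responses, realistic zone geometry, anisotropic climate gradients, or
heavy-tailed production distributions beyond the designed
concentration. Passing tests therefore demonstrate the correctness and
calibration of the machinery under controlled conditions, not
predictive skill on real species data.

### Default study conditions

The end-to-end run (`scripts/acceptance.py`) uses a 60×60-cell world
at 0.1° (~11 km; neighbours conflict under the 20-km rule so thinning
is exercised), 5 predictors with one 0.97-collinear pair, 300 raw
presences from a 5-dimensional Gaussian niche, 4 zones, 2000
background points, the full 50-candidate grid, and a 100-replicate
null test; economics uses 25 municipalities with 3 holding 70% of
product value. Test-suite worlds are smaller (40×40 with 60 presences
for the tuning grid; 20×20 with 30 presences and 50 nulls per repeat
for the null-model calibration, a deliberately scaled-down Monte-Carlo
design; 100×100 with 200 presences for ground-truth recovery).

## Known limitations

- The MaxEnt core aims at the standard penalized objective, not at
  parity with the Java implementation (no threshold/category features,
  no clamping diagnostics, simplified β schedule, permutation
  importance by AUC drop rather than the internal routine).
- Single random train/test split by default (k-fold is available by
  calling `split_train_test` repeatedly); spatial block partitions are
  not implemented.
- Area fractions are cell-count fractions in geographic coordinates,
  not equal-area measures.
- The greedy thinning heuristic above 25 records is not guaranteed
  optimal (its replicate spread is reported); the exact solver is
  limited to small sets by design.
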
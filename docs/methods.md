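# Methods

This note documents the models and procedures implemented in `nipponia`,
the meaning and defaults of the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Geodesy and metrics (`nipponia.geo`)

All distances are great-circle distances on a sphere,
`D = 2r·asin(√(sin²(Δφ/2) + cosφ₁cosφ₂sin²(Δλ/2)))`, with the mean Earth
radius r = 6,371,000 m as the configurable default (the datum choice
moves distances by < 0.5%, far below GPS noise). Coordinates are
geographic degrees; timestamps are naive local civil time throughout —
the diurnal hour rules are defined in the birds' local day, and no
timezone conversion is ever performed.

Model evaluation uses four quantities: R² = 1 − Σ(ŷ−y)²/Σ(ȳ−y)²,
RMSE, MAE, and explained variance EV = 1 − Var(y−ŷ)/Var(y) (population
variances, so EV ≥ R² always, with equality iff the residual mean is
zero). A constant response makes R² undefined; the package raises
rather than returning NaN so that misconfigured pipelines fail fast.

## Synthetic telemetry (`nipponia.simulate`)

The generator emulates the structure of hourly ibis telemetry as a
central-place forager model:

* **Roosts.** A pool of `n_roosts_per_individual` roost sites (default 3)
  is placed uniformly at least `roost_min_sep` = 3 km apart. By default
  the pool is *shared* by all individuals (`share_roosts=True`) — communal
  night roosting is a documented behaviour of the species and gives the
  clustering stage a meaningful target. Each individual switches roosts
  with probability `roost_switch_prob` = 0.15 per day.
* **Foraging.** Each day a foraging site is drawn at a lognormal distance
  from the current roost — median 350 m, σ = 0.567, so the mean is
  ≈ 411 m — at a uniform bearing. σ was fixed once from the
  median/mean pair; the generated distance distribution is the ground
  truth against which the distance-analysis stage is tested.
* **Schedule.** Each hour is placed by the same month-dependent windows
  the classifier uses: night hours at the roost, foraging hours at the
  foraging site, commute (and winter-uncovered) hours linearly
  interpolated between the two (no movement model beyond interpolation is
  claimed). Night hours before noon belong to the previous evening's
  roost.
* **Noise and gaps.** Isotropic Gaussian GPS noise (default SD 25 m) on
  every position; gaps are contiguous missing blocks (default 2–12 h)
  drawn until exactly round(`gap_rate`·n) fixes per individual are
  removed.
* **Geometry.** The simulator works in planar metres around an anchor
  (default 32.2° N, 114.5° E) and converts to lat/lon with the
  equirectangular approximation — at study extents ≤ 20 km the distortion
  is negligible relative to GPS noise.

The **environment** is a square landscape (default 10 km × 10 km at
200 m cells): DEM and NDVI are Gaussian-smoothed white-noise fields
(default kernel 800 m) mapped to 50–500 m elevation and [0.05, 0.95]
NDVI; one river and one road polyline traverse the extent; the expected
fix intensity per cell is log-linear in the z-scored features,
β_ndvi = 1.2, β_dem = 0.8, β_river = 0.6, β_road = 0.4 (positive for
NDVI/DEM, negative for the distances), rescaled to a mean of 30 fixes
per cell; observed counts are Poisson draws.

What the generator does **not** emulate: flight kinematics and movement
autocorrelation within an hour, seasonal migration between regions,
habitat-dependent roost placement, land-cover classes, tag failure
patterns that correlate with behaviour. Tests passing on this generator
therefore demonstrate correctness of the algorithms under the stated
model, not performance on real telemetry.

## Gap imputation (`nipponia.impute`)

The imputer is the six-layer sequence model — LSTM(64) → dropout(0.3) →
LSTM(64) → dropout(0.3) → dense(2) → linear activation — mapping a
window of the last 12 fixes (latitude/longitude, min-max normalized to
[0, 1] per dataset) to the next fix. Implementation is direct on NumPy
arrays (forward pass, backpropagation through time, Adam); the gradients
are verified against central differences in the test suite.

Numerical/training choices:

* **Variational dropout.** One dropout mask per sequence, broadcast over
  timesteps. An independent mask per timestep corrupts the step-to-step
  displacement signal from which the second recurrent layer estimates
  velocity; with per-timestep masks the model could not out-predict a
  last-observation-carried-forward baseline on drifting tracks.
* **Learning rate.** Adam at 5·10⁻³ with per-epoch exponential decay
  0.97 (50 epochs default). The decay matters: dropout keeps the
  gradient noisy, and without decay the final weights inherit that noise.
* **Forget-gate bias 1**, uniform ±1/√H init otherwise; batch 64;
  training pairs are built only from hourly-contiguous stretches.
* **Normalization.** Per-dataset min-max on each coordinate; a constant
  axis (stationary track) is padded by ±10⁻⁴ degrees to stay invertible.
  Predictions are clipped to the normalized unit box, so filled fixes can
  never leave the training bounding box.
* **Filling** is forward-only and iterative: each missing hour is
  predicted from the preceding 12 fixes (observed or already filled) and
  fed back. Gaps at a sequence start with insufficient history are
  skipped with a warning and remain missing. Per-individual training is
  the default; a pooled model is available.
* **Evaluation** scores only imputed rows, by great-circle error against
  held-back truth (gaps are created artificially from observed
  stretches, so truth is always known).

## Activity classification and sites (`nipponia.classify`)

Hour windows (half-open [start, end), night wrapping midnight):

| label | March–October | November–February |
|---|---|---|
| night roost | 21:00–5:00 | 20:00–6:00 |
| foraging | 8:00–16:00 | 9:00–16:00 |
| outing | 5:00–8:00, 16:00–21:00 | 6:00–7:00, 16:00–20:00 |

The half-open convention is the only one that makes the table a
partition (16:00 appears as both a foraging end and an outing start).
The winter windows leave 7:00–9:00 uncovered; such fixes are left
unlabelled and excluded from sites rather than force-assigned. Annual
activity periods are reproductive (Feb–Jun), colonial (Jul–Oct) and
wintering (Nov–Jan); note these partition the year differently from the
two hour-rule month groups — both are applied independently, as defined.

Sites: within one individual's time-ordered stream of one label, a new
site starts when the distance from the previous same-label fix strictly
exceeds 1,000 m (a spacing of exactly 1 km does not split). The site
centroid is the arithmetic mean of member coordinates — adequate at
sub-km extents. A site's activity period is that of its first member.

## Roost clustering (`nipponia.cluster`)

DBSCAN is implemented from scratch with the haversine metric: a point is
core if ≥ `min_samples` points (itself included) lie within `eps`;
clusters are grown breadth-first from core points in input order; border
points reachable from several clusters go to the first cluster that
reaches them in that deterministic scan order (the documented tie rule);
everything else is noise (label −1). The implementation is validated
against a brute-force density-reachability oracle on hundreds of random
instances.

The silhouette coefficient s(i) = (b−a)/max(a, b) is averaged over
non-noise points (singleton-cluster members contribute 0); it is checked
to 10⁻⁹ against both a direct nested-loop evaluation and scikit-learn on
precomputed distance matrices.

Parameter tuning evaluates the full grid (defaults
eps ∈ {100, 200, 500, 1000, 2000} m, min_samples ∈ {3, 4, 5, 10}) and
selects, among combinations with ≥ 2 clusters and noise ratio ≤ 0.2,
the one with the highest silhouette — ties broken by lower noise ratio,
then smaller eps. The two stated goals (silhouette near 1, small noise
ratio) have no published combining rule, so the package realizes them as
this constrained lexicographic selection. The full grid report is always
returned for audit. By default the aggregated night-roost *sites* are
clustered; clustering raw night fixes is available via a flag.

## Distance analysis (`nipponia.distances`)

For every foraging site, the great-circle distance to the nearest
night-roost centroid. Summaries use the sample (n−1) standard deviation
and linear-interpolation ("type 7") quartiles — the convention is stated
because printed quartile values are otherwise ambiguous. The
tail share counts distances strictly above the threshold (default 5 km).

## Habitat model (`nipponia.habitat`)

Cells of a 200 m analysis grid (half-open [edge, edge+size)) are samples
{DEM, road distance, river distance, NDVI; y = fix count}. DEM/NDVI are
sampled at cell centres by nearest neighbour (handling native
resolutions that differ from the grid); road/river distances are
Euclidean distance transforms of the rasterized polylines. Counts are
used untransformed.

Trees are unpruned CART regression trees: at each node, ≤ 3 candidate
features are drawn uniformly without replacement (always fewer than the
4 available) and the split minimizing the children's summed squared
error is found exactly over all midpoints between consecutive distinct
values (cumulative-sum scan; ties broken by lower feature index, then
lower threshold). A node becomes a leaf when it has < 2·min_leaf
samples, a constant response, or no strictly improving split
(tolerance 10⁻¹²). Each of the n_trees (default 300) trees is grown on
a bootstrap sample of size n with replacement (a `bootstrap=False`
switch exists for degenerate diagnostics such as the exact-memorization
check); the forest prediction is the mean over trees, hence always
within the training response range.

Feature **contribution rates** are the per-feature sums of split SSE
decreases, normalized to 1 over the forest — the standard impurity
importance; permutation importance is available as an alternative.
Held-out evaluation uses a random 80/20 cell split. Habitat **ranks**
1–10 are equal-width bins of the min-max-scaled predictions (rank 10
most suitable); the binning is invariant under positive affine
transforms of the predictions, and a decile alternative was deliberately
not made the default because the rating is read as an intensity scale.
Constant predictions collapse to rank 1 with a warning.

**Experiment sizes.** Two standing experiments accompany the model. The
fit-quality experiment uses the default 2,500-cell landscape with a
500-tree forest and reports held-out R²/RMSE/MAE/EV. The
contribution-ordering experiment uses a 16 km × 16 km landscape
(6,400 cells, 600 m smoothing kernel): on smaller landscapes the few
independent field patches let chance correlations between the smooth
features occasionally hand DEM the top contribution even though NDVI has
the largest generating coefficient — with 4× more independent patches
the generative ordering is identifiable (the standing test requires NDVI
first in at least 8 of 10 seeds).
This mirrors the general caution that impurity importances on small,
spatially autocorrelated data sets are realization-noisy.

## Pipeline (`nipponia.pipeline`, CLI `nipponia`)

One YAML config with per-stage sections; a global seed derives
per-stage sub-seeds (SHA-256 of `seed:stage`, < 2³¹), so a rerun with
the same config writes byte-identical artifacts — the manifest records
a SHA-256 checksum per file. Stages read predecessors' artifacts from
the output directory; each CLI subcommand maps to one stage, and
`run-all` chains them. A failing stage aborts with the stage named;
earlier artifacts are preserved.

The habitat stage defaults to `count_source: intensity` — it rates the
landscape from Poisson counts of the generating intensity surface, the
stand-in for the dense multi-year fix map that real telemetry provides.
Gridding the pipeline's own short synthetic trajectories
(`count_source: fixes`) is supported but yields a near-empty count
raster at desk scale (3 individuals × 60 days), which no habitat model
can fit; the option exists for real, dense data sets.

Rasters are serialized as ESRI ASCII grids (plain text, north-up);
polylines and sites as GeoJSON; trajectories as CSV
(`individual_id,timestamp,lat,lon,imputed`, ISO-8601). The package's
raster container and local equirectangular projection are deliberately
minimal — full CRS handling is out of scope.

## Known limitations

* The equirectangular local frame and spherical distances limit use to
  regional extents (≲ 100 km) away from the poles.
* The imputer assumes a strict hourly cadence; sub-hourly or irregular
  sampling is not supported.
* Impurity importances inherit the known biases of CART forests on
  correlated, autocorrelated features; the permutation alternative is
  provided but equally affected by spatial correlation.
* No spatial cross-validation: the 80/20 cell split ignores spatial
  autocorrelation, so held-out metrics on smooth landscapes are
  optimistic relative to truly independent regions.
* Behavioural labels come from clock rules alone, not from movement
  metrics; fixes in the winter 7:00–9:00 window are never classified.
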
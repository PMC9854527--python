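# nipponia

Spatio-temporal trajectory analysis for tracked Crested Ibis
(*Nipponia nippon*) — and, more generally, for hourly GPS telemetry of
central-place foragers. The package turns raw fix tables into an
assessment of where the birds roost, where they forage, and which parts
of a landscape make good habitat:

1. **Gap imputation** — missing hourly fixes are filled by a six-layer
   recurrent sequence model (LSTM → dropout 0.3 → LSTM → dropout 0.3 →
   dense → activation) trained with an MSE loss on min-max-normalized
   latitude/longitude windows; fill quality is measured as great-circle
   error via the haversine distance
   `D = 2r·asin(√(sin²(Δφ/2) + cosφ₁·cosφ₂·sin²(Δλ/2)))`.
2. **Activity classification** — each fix becomes a night-roost,
   foraging or outing point from month-dependent hour windows
   (March–October vs November–February), and consecutive same-label
   fixes more than 1 km apart start a new *site*.
3. **Roost-site mining** — a from-scratch DBSCAN (haversine metric)
   clusters night-roost sites and marks noise; (eps, min_samples) are
   tuned by maximizing the silhouette coefficient subject to a noise-ratio
   cap.
4. **Distance analysis** — nearest-roost distances of foraging sites,
   summarized with mean, SD, quartiles and tail share.
5. **Habitat rating** — fix counts per 200 m grid cell are regressed on
   four features (DEM, road distance, river distance, NDVI) with a
   from-scratch bagged forest of unpruned CART regression trees
   (node split minimizes Σᵥ(y_tv − ŷ_tv)² over candidate features and
   thresholds, ≤ 3 random candidate features per node); predictions are
   evaluated with R², RMSE, MAE and explained variance and normalized to
   habitat ranks 1–10; feature contributions are normalized impurity
   decreases.

Because real tracking data of an endangered species are rarely shareable,
the package ships a **synthetic telemetry + environment generator** with
known ground truth (communal roosts, lognormal roost→forage distances with
median 350 m / mean ≈ 411 m, month-dependent diurnal schedule, GPS noise,
missing blocks, and a landscape whose fix intensity is log-linear in the
environmental features). Every stage is tested against that ground truth.

## Worked example

```bash
nipponia run-all --seed 1 --out run1
```

runs the whole workflow on the default synthetic configuration
(3 individuals × 60 days of hourly fixes, 15% missing, 10 km × 10 km
landscape at 200 m resolution) and writes ~26 artifacts plus a
checksummed `manifest.json`. Key numbers from that run:

```
imputation_eval.json     {"n": 648, "mean_m": 401.06, "median_m": 291.29, "max_m": 3684.71}
clustering.json          {"eps": 100.0, "min_samples": 3, "n_clusters": 3,
                          "silhouette": 0.9832, "noise_ratio": 0.0645}
distance_summary.json    {"n": 44, "mean": 291.05, "sd": 322.61, "median": 195.93, ...}
habitat_metrics.json     {"r2": 0.9728, "rmse": 7.76, "mae": 4.54,
                          "explained_variance": 0.9732, "n_train": 2000, "n_test": 500}
habitat_importances.json {"DEM": 0.151, "Road_Dist": 0.057, "River_Dist": 0.124,
                          "NDVI": 0.667}
```

Reading: the imputer fills 648 artificially removed fixes with ≈ 400 m
mean great-circle error (the birds oscillate between roosts and foraging
sites a few hundred metres apart, so this is the natural error scale);
the tuned DBSCAN recovers exactly the 3 communal roosts that the
generator placed, with near-perfect silhouette; foraging sites sit a few
hundred metres from their nearest roost, echoing the lognormal the
generator draws from; and the habitat forest explains most of the
held-out variance of the landscape point density, ranking NDVI ahead of
DEM and the river/road distances when the generating coefficients are
ordered that way.

The same functionality is available as a library
(`nipponia.simulate`, `.impute`, `.classify`, `.cluster`, `.distances`,
`.habitat`, `.pipeline`) — see `docs/methods.md` for the underlying
models, parameter meanings and limitations.

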
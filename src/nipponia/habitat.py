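"""Grid-based habitat rating with a from-scratch bagged regression forest.

The response is the number of fixes per grid cell (default 200 m); the
four features are elevation (DEM), Euclidean distance to roads, Euclidean
distance to rivers, and NDVI.  Trees are unpruned CART regression trees:
each node searches the midpoints between consecutive sorted distinct
values of a random subset of at most three features (fewer candidate
features than the four available) for the split minimizing the summed
squared deviation of the two children from their means; each tree is
grown on a bootstrap sample of size n drawn with replacement; the forest
prediction is the mean over trees.  Feature contributions are the
normalized total impurity (SSE) decrease; permutation importance is
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .geo import EvalMetrics, regression_metrics
from .raster import LocalFrame, Raster, distance_raster

FEATURES = ["x1_dem", "x2_road_dist", "x3_river_dist", "x4_ndvi"]
FEATURE_NAMES = {"x1_dem": "DEM", "x2_road_dist": "Road_Dist", "x3_river_dist": "River_Dist", "x4_ndvi": "NDVI"}


# ---------------------------------------------------------------------------
# gridding and feature extraction


def grid_counts(
    fixes: pd.DataFrame,
    frame: LocalFrame,
    extent: tuple[float, float],
    cell_size: float = 200.0,
    x0: float = 0.0,
    y0: float = 0.0,
) -> tuple[Raster, int]:
    """Count fixes per half-open grid cell [edge, edge+size).

    Fixes outside the extent are dropped; returns (count raster, number
    dropped).  The raster cell sum equals the number of retained fixes.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx = int(round(extent[0] / cell_size))
    ny = int(round(extent[1] / cell_size))
    grid = Raster(np.zeros((ny, nx)), x0=x0, y0=y0, cell_size=cell_size)
    x, y = frame.to_xy(fixes["lat"].to_numpy(), fixes["lon"].to_numpy())
    i, j = grid.index_of(x, y)
    inside = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (i[inside], j[inside]), 1.0)
    return grid.like(counts), int((~inside).sum())


def extract_features(
    counts: Raster,
    dem: Raster,
    ndvi: Raster,
    rivers: list[LineString],
    roads: list[LineString],
) -> pd.DataFrame:
    """One habitat sample per analysis-grid cell.

    DEM and NDVI are sampled at cell centres by nearest neighbour (which
    also handles co-registered rasters of a different native resolution);
    road/river distances are Euclidean distance transforms of the
    rasterized polylines, in metres.  Columns: ``cell_id``, the four
    features, and the fix count ``y``.
    """
    cx, cy = counts.cell_centers()
    river_d = distance_raster(rivers, counts)
    road_d = distance_raster(roads, counts)
    ny, nx = counts.shape
    return pd.DataFrame(
        {
            "cell_id": np.arange(ny * nx),
            "x1_dem": dem.sample_nearest(cx, cy).ravel(),
            "x2_road_dist": road_d.data.ravel(),
            "x3_river_dist": river_d.data.ravel(),
            "x4_ndvi": ndvi.sample_nearest(cx, cy).ravel(),
            "y": counts.data.ravel().astype(int),
        }
    )


# ---------------------------------------------------------------------------
# CART


def _best_split(X: np.ndarray, y: np.ndarray, candidates: np.ndarray, min_leaf: int):
    """Exact best (feature, threshold) over all midpoint thresholds.

    Minimizes SSE_left + SSE_right (the summed squared deviations of the
    two children from their means) by cumulative sums over each candidate
    feature's sort order.  Returns (feature, threshold, children_sse) or
    None when no admissible split exists.
    """
    n = len(y)
    best = None
    for f in np.sort(candidates):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        c1 = np.cumsum(ys)
        c2 = np.cumsum(ys * ys)
        k = np.arange(1, n)  # left-child sizes
        sse_l = c2[:-1] - c1[:-1] ** 2 / k
        sse_r = (c2[-1] - c2[:-1]) - (c1[-1] - c1[:-1]) ** 2 / (n - k)
        total = np.maximum(sse_l, 0.0) + np.maximum(sse_r, 0.0)
        valid = (xs[:-1] < xs[1:]) & (k >= min_leaf) & (n - k >= min_leaf)
        if not valid.any():
            continue
        total = np.where(valid, total, np.inf)
        pos = int(np.argmin(total))
        if best is None or total[pos] < best[2]:
            best = (int(f), float((xs[pos] + xs[pos + 1]) / 2.0), float(total[pos]))
    return best


def cart_split(
    X: np.ndarray, y: np.ndarray, candidate_features=None, min_leaf: int = 1
):
    """Best CART regression split of a sample subset, or None for a leaf.

    A leaf is returned when the subset is too small (< 2·min_leaf), the
    response is constant, or no candidate split strictly reduces the
    squared-error objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    candidates = (
        np.arange(X.shape[1]) if candidate_features is None else np.asarray(candidate_features)
    )
    sse_parent = float(((y - y.mean()) ** 2).sum())
    if len(y) < 2 * min_leaf or sse_parent <= 1e-12:
        return None
    best = _best_split(X, y, candidates, min_leaf)
    if best is None or sse_parent - best[2] <= 1e-12:
        return None
    return best[0], best[1]


class _Tree:
    """Unpruned CART regression tree on flat node arrays."""

    __slots__ = ("feature", "threshold", "left", "right", "value", "importances")

    def __init__(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                 max_features: int, min_leaf: int):
        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        value: list[float] = []
        imp = np.zeros(X.shape[1])

        def new_node() -> int:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(0.0)
            return len(feature) - 1

        stack = [(np.arange(len(y)), new_node())]
        while stack:
            idx, nid = stack.pop()
            ys = y[idx]
            mean = ys.mean()
            value[nid] = float(mean)
            sse_parent = float(((ys - mean) ** 2).sum())
            if len(idx) < 2 * min_leaf or sse_parent <= 1e-12:
                continue
            cand = rng.choice(X.shape[1], size=max_features, replace=False)
            best = _best_split(X[idx], ys, cand, min_leaf)
            if best is None or sse_parent - best[2] <= 1e-12:
                continue
            f, t, sse_children = best
            feature[nid] = f
            threshold[nid] = t
            imp[f] += sse_parent - sse_children
            go_left = X[idx, f] <= t
            lid, rid = new_node(), new_node()
            left[nid], right[nid] = lid, rid
            stack.append((idx[go_left], lid))
            stack.append((idx[~go_left], rid))

        self.feature = np.array(feature, dtype=np.int64)
        self.threshold = np.array(threshold)
        self.left = np.array(left, dtype=np.int64)
        self.right = np.array(right, dtype=np.int64)
        self.value = np.array(value)
        self.importances = imp

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            f = self.feature[node]
            active = np.flatnonzero(f >= 0)
            if len(active) == 0:
                return self.value[node]
            xa = X[active, f[active]]
            na = node[active]
            node[active] = np.where(xa <= self.threshold[na], self.left[na], self.right[na])


@dataclass
class ForestConfig:
    n_trees: int = 300
    max_features: int = 3  # fewer candidate features than the 4 available
    min_leaf: int = 1
    bootstrap: bool = True  # draw each tree's sample with replacement, size n
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if not 1 <= self.max_features <= 3:
            raise ValueError("max_features must be between 1 and 3")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be at least 1")


class RandomForest:
    """Bag of unpruned CART regression trees; prediction is the tree mean."""

    def __init__(self, config: ForestConfig):
        self.config = config
        self.trees: list[_Tree] = []
        self.feature_importances_: np.ndarray | None = None
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError("need at least 10 samples to fit the forest")
        n = len(y)
        self.n_features_ = X.shape[1]
        rng = np.random.default_rng(self.config.seed)
        self.trees = []
        total_imp = np.zeros(X.shape[1])
        for _ in range(self.config.n_trees):
            boot = rng.integers(0, n, size=n) if self.config.bootstrap else np.arange(n)
            tree = _Tree(X[boot], y[boot], rng, self.config.max_features, self.config.min_leaf)
            self.trees.append(tree)
            total_imp += tree.importances
        if total_imp.sum() > 0:
            self.feature_importances_ = total_imp / total_imp.sum()
        else:
            warnings.warn("no split reduced impurity; uniform importances", stacklevel=2)
            self.feature_importances_ = np.full(X.shape[1], 1.0 / X.shape[1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees:
            raise RuntimeError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)


def fit_forest(samples: pd.DataFrame, config: ForestConfig | None = None) -> RandomForest:
    """Fit the bagged forest on a habitat-sample table (features + ``y``)."""
    config = config or ForestConfig()
    X = samples[FEATURES].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    return RandomForest(config).fit(X, y)


def evaluate_forest(model: RandomForest, samples: pd.DataFrame) -> EvalMetrics:
    """R²/RMSE/MAE/explained-variance of the forest on a held-out table."""
    X = samples[FEATURES].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    return regression_metrics(y, model.predict(X))


def split_samples(
    samples: pd.DataFrame, test_frac: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test cell split."""
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(samples)
    order = rng.permutation(n)
    n_test = max(int(round(test_frac * n)), 1)
    test_idx = order[:n_test]
    train_idx = order[n_test:]
    return samples.iloc[train_idx].reset_index(drop=True), samples.iloc[test_idx].reset_index(drop=True)


def permutation_importance(
    model: RandomForest, samples: pd.DataFrame, seed: int = 0, n_repeats: int = 5
) -> np.ndarray:
    """Alternative contribution measure: mean MSE increase when one
    feature column is shuffled, normalized to sum to 1."""
    rng = np.random.default_rng(seed)
    X = samples[FEATURES].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    base = float(np.mean((y - model.predict(X)) ** 2))
    deltas = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, f] = Xp[rng.permutation(len(y)), f]
            deltas[f] += float(np.mean((y - model.predict(Xp)) ** 2)) - base
    deltas = np.maximum(deltas / n_repeats, 0.0)
    return deltas / deltas.sum() if deltas.sum() > 0 else np.full(X.shape[1], 1.0 / X.shape[1])


def rank_normalize(prediction: Raster | np.ndarray):
    """Habitat rating 1–10: min-max scale then 10 equal-width bins.

    Rank 10 is most suitable; constant predictions collapse to rank 1
    everywhere with a warning.  Invariant under positive affine
    transforms of the predictions.
    """
    arr = prediction.data if isinstance(prediction, Raster) else np.asarray(prediction, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        warnings.warn("constant predictions: all cells assigned rank 1", stacklevel=2)
        ranks = np.ones(arr.shape, dtype=int)
    else:
        scaled = (arr - lo) / (hi - lo)
        ranks = np.minimum(np.floor(scaled * 10.0).astype(int) + 1, 10)
    if isinstance(prediction, Raster):
        return prediction.like(ranks)
    return ranks
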
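"""Gridding, feature extraction and the bagged CART regression forest."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from nipponia import habitat, simulate
from nipponia.habitat import (
    FEATURES,
    ForestConfig,
    cart_split,
    evaluate_forest,
    extract_features,
    fit_forest,
    grid_counts,
    permutation_importance,
    rank_normalize,
    split_samples,
)
from nipponia.raster import LocalFrame, Raster

FRAME = LocalFrame(32.2, 114.5)


def fixes_at(xy_m: np.ndarray) -> pd.DataFrame:
    lat, lon = FRAME.to_latlon(xy_m[:, 0], xy_m[:, 1])
    return pd.DataFrame(
        {
            "individual_id": "a",
            "timestamp": pd.date_range("2021-03-01", periods=len(xy_m), freq="h"),
            "lat": np.atleast_1d(lat),
            "lon": np.atleast_1d(lon),
            "imputed": False,
        }
    )


class TestGridCounts:
    def test_all_fixes_in_one_cell(self):
        pts = np.tile([[350.0, 550.0]], (10, 1))
        counts, dropped = grid_counts(fixes_at(pts), FRAME, (1000.0, 1000.0), 200.0)
        assert dropped == 0
        assert counts.data.sum() == 10
        assert counts.data[2, 1] == 10  # row y in [400,600), col x in [200,400)

    def test_conservation_with_outside_fixes(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-500.0, 1500.0, (200, 2))
        counts, dropped = grid_counts(fixes_at(pts), FRAME, (1000.0, 1000.0), 200.0)
        inside = ((pts >= 0) & (pts < 1000)).all(axis=1).sum()
        assert counts.data.sum() == inside
        assert dropped == 200 - inside

    def test_boundary_goes_to_half_open_cell(self):
        # a coordinate exactly on the 200 m edge belongs to [200, 400)
        grid = Raster(np.zeros((5, 5)), cell_size=200.0)
        i, j = grid.index_of(np.array([200.0, 199.999999]), np.array([0.0, 0.0]))
        assert list(j) == [1, 0]
        assert list(i) == [0, 0]

    def test_bad_cell_size(self):
        with pytest.raises(ValueError):
            grid_counts(fixes_at(np.zeros((1, 2))), FRAME, (1000.0, 1000.0), 0.0)


class TestExtractFeatures:
    def test_river_cell_distance_zero_and_k_cell_bound(self):
        grid = Raster(np.zeros((10, 10)), cell_size=200.0)
        dem = grid.like(np.full((10, 10), 120.0))
        ndvi = grid.like(np.full((10, 10), 0.5))
        river = LineString([(0.0, 500.0), (2000.0, 500.0)])  # crosses row 2
        road = LineString([(500.0, 0.0), (500.0, 2000.0)])  # crosses col 2
        counts = grid.like(np.zeros((10, 10)))
        s = extract_features(counts, dem, ndvi, [river], [road])
        assert len(s) == 100
        tab = s.set_index("cell_id")
        # cell (row 2, col 7) is crossed by the river
        assert tab.loc[2 * 10 + 7, "x3_river_dist"] == 0.0
        # distance grows by one cell_size per cell away from the line
        for k in range(1, 5):
            got = tab.loc[(2 + k) * 10 + 7, "x3_river_dist"]
            assert abs(got - k * 200.0) <= 200.0
        assert (s["x1_dem"] == 120.0).all() and (s["x4_ndvi"] == 0.5).all()


class TestCartSplit:
    def test_perfect_separation(self):
        X = np.array([[10.0, 0], [20.0, 0], [200.0, 0], [210.0, 0]])
        y = np.array([1.0, 1.0, 5.0, 5.0])
        f, t = cart_split(X, y)
        assert f == 0
        assert 20.0 < t < 200.0

    def test_constant_y_is_leaf(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        assert cart_split(X, np.ones(6)) is None

    def test_matches_exhaustive_search_oracle(self):
        """Chosen split attains the exhaustively-computed minimum of the
        children's summed squared error on 100 random 20-sample sets."""
        rng = np.random.default_rng(1)

        def sse(v):
            return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0

        for trial in range(100):
            X = rng.normal(size=(20, 4))
            y = rng.normal(size=20) + 2.0 * X[:, rng.integers(0, 4)]
            got = cart_split(X, y)
            best_obj, best_pairs = np.inf, []
            for f in range(4):
                xs = np.unique(X[:, f])
                for a, b in zip(xs[:-1], xs[1:]):
                    t = (a + b) / 2.0
                    obj = sse(y[X[:, f] <= t]) + sse(y[X[:, f] > t])
                    if obj < best_obj - 1e-12:
                        best_obj, best_pairs = obj, [(f, t)]
                    elif abs(obj - best_obj) <= 1e-12:
                        best_pairs.append((f, t))
            assert got is not None, trial
            gf, gt = got
            obj_got = sse(y[X[:, gf] <= gt]) + sse(y[X[:, gf] > gt])
            assert obj_got == pytest.approx(best_obj, rel=1e-9, abs=1e-9), trial


class TestForest:
    @staticmethod
    def _samples(n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = np.round(np.abs(3.0 * X[:, 0] - 2.0 * X[:, 3] + rng.normal(0, 0.3, n)))
        return pd.DataFrame(
            {"cell_id": np.arange(n), **{f: X[:, k] for k, f in enumerate(FEATURES)}, "y": y}
        )

    def test_single_tree_memorizes_distinct_rows(self):
        """An unpruned tree grown on the samples themselves reproduces every
        training response exactly (training R^2 = 1)."""
        s = self._samples()
        model = fit_forest(
            s, ForestConfig(n_trees=1, min_leaf=1, max_features=3, bootstrap=False, seed=0)
        )
        m = evaluate_forest(model, s)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_importances_normalized(self):
        model = fit_forest(self._samples(), ForestConfig(n_trees=20, seed=1))
        imp = model.feature_importances_
        assert np.all(imp >= 0.0)
        assert imp.sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        s = self._samples()
        m1 = fit_forest(s, ForestConfig(n_trees=10, seed=3))
        m2 = fit_forest(s, ForestConfig(n_trees=10, seed=3))
        X = s[FEATURES].to_numpy(float)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_prediction_bounded_by_training_range(self):
        s = self._samples()
        model = fit_forest(s, ForestConfig(n_trees=15, seed=2))
        rng = np.random.default_rng(9)
        X = rng.normal(scale=5.0, size=(50, 4))  # far outside training data
        pred = model.predict(X)
        assert pred.min() >= s["y"].min() - 1e-9
        assert pred.max() <= s["y"].max() + 1e-9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ForestConfig(max_features=4)  # must use fewer than the 4 features
        with pytest.raises(ValueError):
            ForestConfig(n_trees=0)
        with pytest.raises(ValueError):
            fit_forest(self._samples(n=5), ForestConfig())

    def test_importances_close_to_sklearn_reference(self):
        """Impurity importances within 0.05 of sklearn's on the same data
        (same estimator family, independent implementation)."""
        from sklearn.ensemble import RandomForestRegressor

        s = self._samples(n=150, seed=4)
        X = s[FEATURES].to_numpy(float)
        y = s["y"].to_numpy(float)
        ours = fit_forest(s, ForestConfig(n_trees=100, max_features=3, seed=0))
        ref = RandomForestRegressor(n_estimators=100, max_features=3, random_state=0).fit(X, y)
        assert np.max(np.abs(ours.feature_importances_ - ref.feature_importances_)) < 0.05

    def test_permutation_importance_ranks_signal_features(self):
        s = self._samples(n=200, seed=5)
        model = fit_forest(s, ForestConfig(n_trees=50, seed=1))
        pi = permutation_importance(model, s, seed=0)
        assert pi.sum() == pytest.approx(1.0)
        assert {int(np.argsort(pi)[-1]), int(np.argsort(pi)[-2])} == {0, 3}

    def test_more_trees_do_not_degrade_heldout_rmse(self):
        """Held-out RMSE with 500 trees stays within 5% of 50 trees."""
        env = simulate.simulate_environment(seed=31)
        counts = simulate.sample_counts(env, seed=32)
        s = extract_features(counts, env.dem, env.ndvi, [env.river], [env.road])
        train, test = split_samples(s, 0.2, seed=1)
        r50 = evaluate_forest(fit_forest(train, ForestConfig(n_trees=50, seed=2)), test).rmse
        r500 = evaluate_forest(fit_forest(train, ForestConfig(n_trees=500, seed=2)), test).rmse
        assert r500 <= 1.05 * r50


class TestRankNormalize:
    def test_closed_form_binning(self):
        pred = np.array([0.0, 55.0, 100.0])
        ranks = rank_normalize(pred)
        assert list(ranks) == [1, 6, 10]

    def test_affine_invariance_and_range(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(size=(20, 20))
        r1 = rank_normalize(pred)
        r2 = rank_normalize(3.5 * pred + 11.0)
        assert np.array_equal(r1, r2)
        assert set(np.unique(r1)) <= set(range(1, 11))

    def test_monotone(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(size=100)
        ranks = rank_normalize(pred)
        order = np.argsort(pred)
        assert (np.diff(ranks[order]) >= 0).all()

    def test_constant_prediction_warns_rank_one(self):
        with pytest.warns(UserWarning, match="constant"):
            ranks = rank_normalize(np.full(9, 3.0))
        assert (ranks == 1).all()

    def test_raster_roundtrip(self):
        grid = Raster(np.arange(9.0).reshape(3, 3), cell_size=100.0)
        out = rank_normalize(grid)
        assert isinstance(out, Raster)
        assert out.data[0, 0] == 1 and out.data[2, 2] == 10
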
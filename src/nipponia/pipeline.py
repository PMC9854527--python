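"""End-to-end workflow: simulate → impute → classify → cluster → distances
→ habitat, with per-stage artifacts, structured logging and a checksummed
manifest.

One YAML config file with per-stage sections drives a run; a global seed
deterministically derives each stage's sub-seed, so a rerun with the same
config reproduces identical artifact checksums.  Stages read their
predecessors' artifacts from the output directory, so they can also be
run one at a time (the CLI maps one subcommand to one stage).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, cluster, distances, habitat, impute, simulate
from .geo import read_fixes, write_fixes
from .raster import LocalFrame, lines_to_geojson, points_to_geojson, read_ascii_grid, write_ascii_grid

log = logging.getLogger("nipponia")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {
        "n_individuals": 3,
        "n_days": 60,
        "n_roosts_per_individual": 3,
        "roost_switch_prob": 0.15,
        "forage_dist_lognormal": [350.0, 0.567],
        "gps_noise_sd": 25.0,
        "gap_rate": 0.15,
        "gap_block_len": [2, 12],
        "start_date": "2021-03-01",
        "anchor_lat": 32.2,
        "anchor_lon": 114.5,
        "extent": 10000.0,
        "roost_min_sep": 3000.0,
    },
    "environment": {
        "extent": [10000.0, 10000.0],
        "cell_size": 200.0,
        "smooth_kernel_m": 800.0,
        "betas": {"ndvi": 1.2, "dem": 0.8, "river": 0.6, "road": 0.4, "mean_intensity": 30.0},
    },
    "imputation": {
        "enabled": True,
        "pooled": False,
        "window_len": 12,
        "hidden_units": 64,
        "dropout_p": 0.3,
        "epochs": 50,
        "batch_size": 64,
        "learning_rate": 1.0e-3,
    },
    "classification": {"threshold_m": 1000.0},
    "clustering": {
        "eps_grid": [100.0, 200.0, 500.0, 1000.0, 2000.0],
        "min_samples_grid": [3, 4, 5, 10],
        "noise_cap": 0.2,
        "use_raw_fixes": False,
    },
    "distances": {"threshold_m": 5000.0},
    "habitat": {
        # "intensity": rate habitat from the landscape point-density surface
        # (Poisson counts of the generating intensity, emulating a dense
        # multi-year fix map); "fixes": grid the pipeline's own trajectory
        # fixes (desk-scale tracks are usually too sparse for a stable fit).
        "count_source": "intensity",
        "n_trees": 300,
        "max_features": 3,
        "min_leaf": 1,
        "test_frac": 0.2,
    },
}

STAGES = ["simulate", "impute", "classify", "cluster", "distances", "habitat"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the defaults (deep merge)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Run stages against one output directory, collecting a manifest."""

    def __init__(self, config: dict, out_dir):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[dict] = []
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        self._log_handler = handler

    def close(self) -> None:
        log.removeHandler(self._log_handler)
        self._log_handler.close()

    def _record(self, path: Path, stage: str) -> Path:
        self.artifacts.append({"path": path.name, "stage": stage, "sha256": _sha256(path)})
        return path

    def _path(self, name: str) -> Path:
        return self.out / name

    # ---- stages ----------------------------------------------------------

    def run_simulate(self) -> None:
        stage = "simulate"
        log.info("stage=%s start params=%s", stage, self.cfg["simulation"])
        sim = dict(self.cfg["simulation"])
        sim["forage_dist_lognormal"] = tuple(sim["forage_dist_lognormal"])
        sim["gap_block_len"] = tuple(sim["gap_block_len"])
        config = simulate.SimConfig(**sim, seed=stage_seed(self.cfg["seed"], "simulate"))
        fixes, truth = simulate.simulate_trajectories(config)

        env_cfg = self.cfg["environment"]
        betas = simulate.EnvBetas(**env_cfg["betas"])
        env = simulate.simulate_environment(
            extent=tuple(env_cfg["extent"]),
            cell_size=env_cfg["cell_size"],
            betas=betas,
            seed=stage_seed(self.cfg["seed"], "environment"),
            smooth_kernel_m=env_cfg["smooth_kernel_m"],
            anchor_lat=sim["anchor_lat"],
            anchor_lon=sim["anchor_lon"],
        )

        write_fixes(fixes, self._path("trajectories_true.csv"))
        self._record(self._path("trajectories_true.csv"), stage)
        states = fixes.assign(state=truth.states.values)
        write_fixes(states, self._path("trajectories_states.csv"))
        self._record(self._path("trajectories_states.csv"), stage)

        gapped, mask = simulate.inject_gaps(
            fixes,
            gap_rate=sim["gap_rate"],
            gap_block_len=sim["gap_block_len"],
            seed=stage_seed(self.cfg["seed"], "gaps"),
        )
        write_fixes(gapped, self._path("trajectories_gapped.csv"))
        self._record(self._path("trajectories_gapped.csv"), stage)
        mask_out = mask.copy()
        mask_out["timestamp"] = pd.to_datetime(mask_out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        mask_out.to_csv(self._path("gap_mask.csv"), index=False)
        self._record(self._path("gap_mask.csv"), stage)

        for name, rast in [
            ("dem.asc", env.dem),
            ("ndvi.asc", env.ndvi),
            ("river_dist.asc", env.river_dist),
            ("road_dist.asc", env.road_dist),
            ("intensity.asc", env.intensity),
        ]:
            write_ascii_grid(rast, self._path(name))
            self._record(self._path(name), stage)
        lines_to_geojson({"river": env.river, "road": env.road}, env.frame, self._path("waterways_roads.geojson"))
        self._record(self._path("waterways_roads.geojson"), stage)

        truth_doc = {
            "roosts": {ind: arr.tolist() for ind, arr in truth.roosts.items()},
            "betas": betas.as_dict(),
            "forage_distance_m": {
                "median_config": sim["forage_dist_lognormal"][0],
                "sigma_config": sim["forage_dist_lognormal"][1],
                "mean_generated": float(truth.forage_sites["distance_m"].mean()),
            },
        }
        with open(self._path("ground_truth.json"), "w") as fh:
            json.dump(truth_doc, fh, indent=1)
        self._record(self._path("ground_truth.json"), stage)
        log.info("stage=%s done fixes=%d gaps=%d", stage, len(fixes), len(mask))

    def run_impute(self) -> None:
        stage = "impute"
        cfg = self.cfg["imputation"]
        gapped = read_fixes(self._path("trajectories_gapped.csv"))
        mask = pd.read_csv(self._path("gap_mask.csv"), parse_dates=["timestamp"])
        if not cfg.get("enabled", True) or len(mask) == 0:
            log.info("stage=%s pass-through (disabled or no gaps)", stage)
            write_fixes(gapped, self._path("trajectories_completed.csv"))
            self._record(self._path("trajectories_completed.csv"), stage)
            return
        iconf = impute.ImputerConfig(
            window_len=cfg["window_len"],
            hidden_units=cfg["hidden_units"],
            dropout_p=cfg["dropout_p"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"],
            seed=stage_seed(self.cfg["seed"], "impute"),
        )
        log.info("stage=%s start config=%s pooled=%s", stage, iconf, cfg["pooled"])
        histories = {}
        if cfg["pooled"]:
            model = impute.build_imputer(iconf)
            model, norm, hist = impute.fit_imputer(model, gapped, iconf)
            completed = impute.fill_gaps(model, gapped, mask, norm)
            histories["pooled"] = hist
        else:
            parts = []
            for ind, grp in gapped.groupby("individual_id", sort=True):
                model = impute.build_imputer(iconf)
                model, norm, hist = impute.fit_imputer(model, grp, iconf)
                parts.append(
                    impute.fill_gaps(model, grp, mask[mask["individual_id"] == ind], norm)
                )
                histories[ind] = hist
            completed = pd.concat(parts).reset_index(drop=True)
        write_fixes(completed, self._path("trajectories_completed.csv"))
        self._record(self._path("trajectories_completed.csv"), stage)
        pd.DataFrame(histories).to_csv(self._path("loss_history.csv"), index_label="epoch")
        self._record(self._path("loss_history.csv"), stage)

        truth = read_fixes(self._path("trajectories_true.csv"))
        metrics = impute.evaluate_imputation(completed, truth)
        with open(self._path("imputation_eval.json"), "w") as fh:
            json.dump(metrics, fh, indent=1)
        self._record(self._path("imputation_eval.json"), stage)
        log.info("stage=%s done mean_error_m=%.1f", stage, metrics["mean_m"])

    def run_classify(self) -> None:
        stage = "classify"
        completed = read_fixes(self._path("trajectories_completed.csv"))
        labeled = classify.label_fixes(completed)
        sites = classify.segment_sites(labeled, threshold=self.cfg["classification"]["threshold_m"])
        site_of_fix = pd.Series(-1, index=labeled.index)
        for s in sites:
            site_of_fix.loc[s.member_index] = s.site_id
        labeled["site_id"] = site_of_fix
        out = labeled.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(self._path("fixes_labeled.csv"), index=False)
        self._record(self._path("fixes_labeled.csv"), stage)
        recs = classify.sites_to_frame(sites).to_dict("records")
        points_to_geojson(recs, self._path("sites.geojson"))
        self._record(self._path("sites.geojson"), stage)
        log.info("stage=%s done sites=%d", stage, len(sites))

    def _load_sites(self) -> pd.DataFrame:
        with open(self._path("sites.geojson")) as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc["features"]:
            props = dict(feat["properties"])
            props["lon"], props["lat"] = feat["geometry"]["coordinates"]
            rows.append(props)
        return pd.DataFrame(rows)

    def run_cluster(self) -> None:
        stage = "cluster"
        ccfg = self.cfg["clustering"]
        if ccfg["use_raw_fixes"]:
            labeled = pd.read_csv(self._path("fixes_labeled.csv"))
            night = labeled[labeled["label"] == classify.NIGHT_ROOST]
        else:
            sites = self._load_sites()
            night = sites[sites["label"] == classify.NIGHT_ROOST]
        pts = night[["lat", "lon"]].to_numpy(dtype=float)
        log.info("stage=%s start n_points=%d", stage, len(pts))
        try:
            params, result, report = cluster.tune_parameters(
                pts,
                eps_grid=ccfg["eps_grid"],
                min_samples_grid=ccfg["min_samples_grid"],
                noise_cap=ccfg["noise_cap"],
            )
        except cluster.TuningError as exc:
            exc.report.to_csv(self._path("clustering_report.csv"), index=False)
            raise PipelineError(f"stage cluster failed: {exc}") from exc
        report.to_csv(self._path("clustering_report.csv"), index=False)
        self._record(self._path("clustering_report.csv"), stage)
        clustered = night.copy()
        clustered["cluster"] = result.labels
        points_to_geojson(clustered.to_dict("records"), self._path("roost_clusters.geojson"))
        self._record(self._path("roost_clusters.geojson"), stage)
        with open(self._path("clustering.json"), "w") as fh:
            json.dump(
                {
                    "eps": params.eps,
                    "min_samples": params.min_samples,
                    "n_clusters": result.n_clusters,
                    "silhouette": result.silhouette,
                    "noise_ratio": result.noise_ratio,
                },
                fh,
                indent=1,
            )
        self._record(self._path("clustering.json"), stage)
        log.info(
            "stage=%s done n_clusters=%d silhouette=%.3f noise=%.3f",
            stage, result.n_clusters, result.silhouette, result.noise_ratio,
        )

    def run_distances(self) -> None:
        stage = "distances"
        sites = self._load_sites()
        roost = sites[sites["label"] == classify.NIGHT_ROOST]
        forage = sites[sites["label"] == classify.FORAGING]
        if len(roost) == 0 or len(forage) == 0:
            raise PipelineError("stage distances failed: missing roost or foraging sites")
        rl = [classify.SitePoint(0, "", classify.NIGHT_ROOST, r.lat, r.lon, [], None, None, "")
              for r in roost.itertuples()]
        fl = [classify.SitePoint(0, "", classify.FORAGING, r.lat, r.lon, [], None, None, "")
              for r in forage.itertuples()]
        d = distances.nearest_roost_distances(fl, rl)
        summary = distances.summarize_distances(d, threshold=self.cfg["distances"]["threshold_m"])
        with open(self._path("distance_summary.json"), "w") as fh:
            json.dump(summary.as_dict(), fh, indent=1)
        self._record(self._path("distance_summary.json"), stage)
        forage_out = forage.copy()
        forage_out["nearest_roost_m"] = d
        points_to_geojson(forage_out.to_dict("records"), self._path("foraging_distances.geojson"))
        self._record(self._path("foraging_distances.geojson"), stage)
        log.info("stage=%s done n=%d mean=%.1f sd=%.1f", stage, summary.n, summary.mean, summary.sd)

    def run_habitat(self) -> None:
        stage = "habitat"
        hcfg = self.cfg["habitat"]
        env_cfg = self.cfg["environment"]
        sim_cfg = self.cfg["simulation"]
        completed = read_fixes(self._path("trajectories_completed.csv"))
        frame = LocalFrame(sim_cfg["anchor_lat"], sim_cfg["anchor_lon"])
        dem = read_ascii_grid(self._path("dem.asc"))
        ndvi = read_ascii_grid(self._path("ndvi.asc"))
        with open(self._path("waterways_roads.geojson")) as fh:
            doc = json.load(fh)
        from shapely.geometry import LineString

        lines = {}
        for feat in doc["features"]:
            lon, lat = zip(*feat["geometry"]["coordinates"])
            x, y = frame.to_xy(np.array(lat), np.array(lon))
            lines[feat["properties"]["name"]] = LineString(np.column_stack([x, y]))

        source = hcfg.get("count_source", "intensity")
        if source == "fixes":
            counts, dropped = habitat.grid_counts(
                completed, frame, tuple(env_cfg["extent"]), cell_size=env_cfg["cell_size"]
            )
            log.info("stage=%s gridded fixes (dropped outside extent: %d)", stage, dropped)
        elif source == "intensity":
            intensity = read_ascii_grid(self._path("intensity.asc"))
            rng = np.random.default_rng(stage_seed(self.cfg["seed"], "habitat_counts"))
            counts = intensity.like(rng.poisson(intensity.data).astype(float))
            log.info("stage=%s sampled landscape counts from intensity", stage)
        else:
            raise PipelineError(f"stage habitat failed: unknown count_source {source!r}")
        samples = habitat.extract_features(counts, dem, ndvi, [lines["river"]], [lines["road"]])
        samples.to_csv(self._path("habitat_samples.csv"), index=False)
        self._record(self._path("habitat_samples.csv"), stage)

        fconf = habitat.ForestConfig(
            n_trees=hcfg["n_trees"],
            max_features=hcfg["max_features"],
            min_leaf=hcfg["min_leaf"],
            seed=stage_seed(self.cfg["seed"], "habitat"),
        )
        train, test = habitat.split_samples(
            samples, test_frac=hcfg["test_frac"], seed=stage_seed(self.cfg["seed"], "habitat_split")
        )
        model = habitat.fit_forest(train, fconf)
        metrics = habitat.evaluate_forest(model, test)
        with open(self._path("habitat_metrics.json"), "w") as fh:
            json.dump({**metrics.as_dict(), "n_train": len(train), "n_test": len(test)}, fh, indent=1)
        self._record(self._path("habitat_metrics.json"), stage)
        importances = {
            habitat.FEATURE_NAMES[f]: float(v)
            for f, v in zip(habitat.FEATURES, model.feature_importances_)
        }
        with open(self._path("habitat_importances.json"), "w") as fh:
            json.dump(importances, fh, indent=1)
        self._record(self._path("habitat_importances.json"), stage)

        pred = counts.like(model.predict(samples[habitat.FEATURES].to_numpy(float)).reshape(counts.shape))
        write_ascii_grid(pred, self._path("habitat_prediction.asc"))
        self._record(self._path("habitat_prediction.asc"), stage)
        ranks = habitat.rank_normalize(pred)
        write_ascii_grid(ranks, self._path("habitat_rank.asc"))
        self._record(self._path("habitat_rank.asc"), stage)
        log.info("stage=%s done r2=%.3f importances=%s", stage, metrics.r2, importances)

    # ---- orchestration ---------------------------------------------------

    _STAGE_FUNCS = {
        "simulate": run_simulate,
        "impute": run_impute,
        "classify": run_classify,
        "cluster": run_cluster,
        "distances": run_distances,
        "habitat": run_habitat,
    }

    def run_stage(self, stage: str) -> None:
        if stage not in self._STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            self._STAGE_FUNCS[stage](self)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    def run_all(self) -> dict:
        for stage in STAGES:
            self.run_stage(stage)
        return self.write_manifest()

    def write_manifest(self) -> dict:
        manifest = {"seed": self.cfg["seed"], "artifacts": self.artifacts}
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages; returns the artifact manifest."""
    pipe = Pipeline(config, out_dir)
    try:
        return pipe.run_all()
    finally:
        pipe.close()
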
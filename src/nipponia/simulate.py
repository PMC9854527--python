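"""Synthetic telemetry and environment with known ground truth.

The generator emulates the structure of hourly ibis tracking data:

* a small pool of fixed night-roost sites (kilometres apart) is shared by
  all individuals by default — tracked ibis are known to share roosts —
  and each individual switches roost with a small daily probability;
* each day it forages at a site drawn at a lognormal distance (median
  350 m, sigma 0.567, giving mean ≈ 411 m) and uniform bearing from the
  current roost — the central-place-forager structure;
* the hour-of-day schedule follows the month-dependent windows used by the
  classifier: night hours sit at the roost, foraging hours at the foraging
  site, commute hours interpolate linearly between them;
* every position gets isotropic Gaussian GPS noise;
* gaps are injected as contiguous missing blocks;
* the environment is a smooth random landscape (DEM, NDVI, one river and
  one road polyline) whose expected fix intensity per cell is log-linear in
  the standardized features, with coefficient ordering
  NDVI > DEM > river distance > road distance by default.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from . import classify
from .raster import LocalFrame, Raster, distance_raster


@dataclass
class SimConfig:
    """Trajectory-simulation settings (all lengths in metres)."""

    n_individuals: int = 3
    n_days: int = 60
    fixes_per_day: int = 24
    n_roosts_per_individual: int = 3
    roost_switch_prob: float = 0.15
    forage_dist_lognormal: tuple[float, float] = (350.0, 0.567)  # (median m, sigma)
    gps_noise_sd: float = 25.0
    gap_rate: float = 0.15
    gap_block_len: tuple[int, int] = (2, 12)
    seed: int = 0
    start_date: str = "2021-03-01"
    anchor_lat: float = 32.2
    anchor_lon: float = 114.5
    extent: float = 10_000.0
    roost_min_sep: float = 3_000.0
    share_roosts: bool = True  # individuals draw from one communal roost pool

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_days < 1:
            raise ValueError("need at least one individual and one day")
        if not 0.0 <= self.roost_switch_prob <= 1.0:
            raise ValueError("roost_switch_prob must be a probability")
        if not 0.0 <= self.gap_rate <= 0.5:
            raise ValueError("gap_rate must lie in [0, 0.5]")
        if self.forage_dist_lognormal[0] <= 0:
            raise ValueError("foraging-distance median must be positive")
        if self.fixes_per_day < 1 or 24 % self.fixes_per_day != 0:
            raise ValueError("fixes_per_day must divide 24")
        if self.n_roosts_per_individual < 1:
            raise ValueError("need at least one roost per individual")

    @property
    def frame(self) -> LocalFrame:
        return LocalFrame(self.anchor_lat, self.anchor_lon)


@dataclass
class GroundTruth:
    """Per-fix behavioural states and the generating site geometry."""

    states: pd.Series                 # 'roost' | 'forage' | 'transit', aligned to fixes
    roosts: dict                      # individual_id -> (k, 2) array of (lat, lon)
    forage_sites: pd.DataFrame        # individual_id, day, lat, lon, roost_idx, distance_m
    betas: dict | None = None         # filled when an environment is attached


def _place_roosts(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Rejection-sample roost coordinates at least roost_min_sep apart."""
    lo, hi = 0.1 * cfg.extent, 0.9 * cfg.extent
    for _ in range(10_000):
        pts = rng.uniform(lo, hi, size=(cfg.n_roosts_per_individual, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if cfg.n_roosts_per_individual == 1 or d.min() >= cfg.roost_min_sep:
            return pts
    raise ValueError("cannot place roosts with the requested minimum separation")


def simulate_trajectories(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the hourly fix table and its ground truth.

    Night-window hours before noon use the *previous* day's roost (the
    night that began the evening before); the daily roost switch, when it
    happens, takes effect from the morning commute onward.
    """
    rng = np.random.default_rng(config.seed)
    frame = config.frame
    start = pd.Timestamp(config.start_date)
    hours = np.arange(0, 24, 24 // config.fixes_per_day)
    median, sigma = config.forage_dist_lognormal

    rows: list[tuple] = []
    states: list[str] = []
    roosts: dict[str, np.ndarray] = {}
    forage_rows: list[dict] = []

    shared_pool = _place_roosts(rng, config) if config.share_roosts else None

    for i in range(config.n_individuals):
        ind = f"ibis{i:02d}"
        roost_xy = shared_pool if shared_pool is not None else _place_roosts(rng, config)
        lat_r, lon_r = frame.to_latlon(roost_xy[:, 0], roost_xy[:, 1])
        roosts[ind] = np.column_stack([lat_r, lon_r])

        current = int(rng.integers(config.n_roosts_per_individual))
        roost_of_day = []
        day_forage = []
        for d in range(config.n_days):
            if d > 0 and config.n_roosts_per_individual > 1 and rng.random() < config.roost_switch_prob:
                others = [k for k in range(config.n_roosts_per_individual) if k != current]
                current = int(others[rng.integers(len(others))])
            roost_of_day.append(current)
            dist = float(rng.lognormal(mean=math.log(median), sigma=sigma))
            bearing = rng.uniform(0.0, 2.0 * math.pi)
            fxy = roost_xy[current] + dist * np.array([math.cos(bearing), math.sin(bearing)])
            day_forage.append(fxy)
            flat, flon = frame.to_latlon(fxy[0], fxy[1])
            forage_rows.append(
                {
                    "individual_id": ind,
                    "day": d,
                    "lat": float(flat),
                    "lon": float(flon),
                    "roost_idx": current,
                    "distance_m": dist,
                }
            )

        for d in range(config.n_days):
            day_ts = start + pd.Timedelta(days=d)
            labels = [
                classify.classify_fix(day_ts + pd.Timedelta(hours=int(h))) for h in hours
            ]
            # commute/unlabelled hours interpolate roost->forage (am) or back (pm)
            am_transit = [h for h, lb in zip(hours, labels) if lb not in (classify.NIGHT_ROOST, classify.FORAGING) and h < 12]
            pm_transit = [h for h, lb in zip(hours, labels) if lb not in (classify.NIGHT_ROOST, classify.FORAGING) and h >= 12]
            night_roost_xy_am = roost_xy[roost_of_day[max(d - 1, 0)]]
            night_roost_xy_pm = roost_xy[roost_of_day[d]]
            fxy = day_forage[d]
            for h, lb in zip(hours, labels):
                ts = day_ts + pd.Timedelta(hours=int(h))
                if lb == classify.NIGHT_ROOST:
                    xy = night_roost_xy_am if h < 12 else night_roost_xy_pm
                    state = "roost"
                elif lb == classify.FORAGING:
                    xy = fxy
                    state = "forage"
                elif h < 12:
                    frac = (am_transit.index(h) + 1) / (len(am_transit) + 1)
                    xy = night_roost_xy_am + frac * (fxy - night_roost_xy_am)
                    state = "transit"
                else:
                    frac = (pm_transit.index(h) + 1) / (len(pm_transit) + 1)
                    xy = fxy + frac * (night_roost_xy_pm - fxy)
                    state = "transit"
                if config.gps_noise_sd > 0:
                    xy = xy + rng.normal(0.0, config.gps_noise_sd, size=2)
                lat, lon = frame.to_latlon(xy[0], xy[1])
                rows.append((ind, ts, float(lat), float(lon), False))
                states.append(state)

    fixes = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lat", "lon", "imputed"])
    truth = GroundTruth(
        states=pd.Series(states, index=fixes.index, name="state"),
        roosts=roosts,
        forage_sites=pd.DataFrame(forage_rows),
    )
    return fixes, truth


def inject_gaps(
    fixes: pd.DataFrame,
    gap_rate: float,
    gap_block_len: tuple[int, int] = (2, 12),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove contiguous blocks of fixes per individual.

    Returns ``(gapped, mask)`` where ``mask`` holds the
    (individual_id, timestamp) rows that were removed; the union of the two
    restores the original table.  The removed fraction per individual
    equals round(gap_rate · n) exactly (blocks are drawn until the target
    is reached, then trimmed).
    """
    if not 0.0 <= gap_rate < 1.0:
        raise ValueError("gap_rate must lie in [0, 1)")
    if gap_rate == 0.0:
        return fixes.copy(), fixes.iloc[0:0][["individual_id", "timestamp"]].copy()
    rng = np.random.default_rng(seed)
    lo, hi = gap_block_len
    removed_parts = []
    kept_parts = []
    for _, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        n = len(grp)
        target = int(round(gap_rate * n))
        removed = np.zeros(n, dtype=bool)
        tries = 0
        while removed.sum() < target and tries < 10_000:
            length = int(rng.integers(lo, hi + 1))
            length = min(length, n)
            startpos = int(rng.integers(0, n - length + 1))
            removed[startpos : startpos + length] = True
            tries += 1
        extra = int(removed.sum()) - target
        if extra > 0:
            marked = np.flatnonzero(removed)
            removed[marked[-extra:]] = False
        removed_parts.append(grp.loc[removed])
        kept_parts.append(grp.loc[~removed])
    gapped = pd.concat(kept_parts).sort_values(["individual_id", "timestamp"]).reset_index(drop=True)
    mask = (
        pd.concat(removed_parts)[["individual_id", "timestamp"]]
        .sort_values(["individual_id", "timestamp"])
        .reset_index(drop=True)
    )
    return gapped, mask


# ---------------------------------------------------------------------------
# environment


@dataclass
class EnvBetas:
    """Log-linear coefficients of the expected fix intensity per cell.

    Intensity ∝ exp(β_ndvi·z(NDVI) + β_dem·z(DEM) − β_river·z(d_river)
    − β_road·z(d_road)) rescaled so the landscape mean equals
    ``mean_intensity`` fixes per cell.  Defaults follow the importance
    ordering NDVI > DEM > river > road.
    """

    ndvi: float = 1.2
    dem: float = 0.8
    river: float = 0.6
    road: float = 0.4
    mean_intensity: float = 30.0

    def as_dict(self) -> dict[str, float]:
        return {
            "ndvi": self.ndvi,
            "dem": self.dem,
            "river": self.river,
            "road": self.road,
            "mean_intensity": self.mean_intensity,
        }


@dataclass
class Environment:
    """Raster/vector landscape bundle plus the generating intensity."""

    dem: Raster
    ndvi: Raster
    river: LineString
    road: LineString
    river_dist: Raster
    road_dist: Raster
    intensity: Raster
    betas: EnvBetas
    frame: LocalFrame


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _meander(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=5.0, mode="reflect") * amplitude


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def simulate_environment(
    extent: tuple[float, float] = (10_000.0, 10_000.0),
    cell_size: float = 200.0,
    betas: EnvBetas | None = None,
    seed: int = 0,
    smooth_kernel_m: float = 800.0,
    anchor_lat: float = 32.2,
    anchor_lon: float = 114.5,
) -> Environment:
    """Generate the landscape rasters, polylines and expected intensity.

    DEM spans roughly 50–500 m elevation, NDVI lies in [0, 1]; both are
    Gaussian-smoothed white-noise fields.  One river and one road polyline
    traverse the extent.  ``extent`` must be divisible by ``cell_size``.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    ex, ey = float(extent[0]), float(extent[1])
    if ex % cell_size or ey % cell_size:
        raise ValueError("extent must be divisible by cell_size")
    betas = betas or EnvBetas()
    rng = np.random.default_rng(seed)
    nx, ny = int(ex / cell_size), int(ey / cell_size)
    sigma_cells = smooth_kernel_m / cell_size

    grid = Raster(np.zeros((ny, nx)), x0=0.0, y0=0.0, cell_size=cell_size)
    dem_z = _smooth_field(rng, (ny, nx), sigma_cells)
    ndvi_z = _smooth_field(rng, (ny, nx), sigma_cells)
    dem = grid.like(50.0 + (dem_z - dem_z.min()) / (dem_z.max() - dem_z.min()) * 450.0)
    ndvi = grid.like(0.05 + (ndvi_z - ndvi_z.min()) / (ndvi_z.max() - ndvi_z.min()) * 0.90)

    xs = np.linspace(0.0, ex, 60)
    river = LineString(np.column_stack([xs, 0.45 * ey + _meander(rng, 60, 0.18 * ey)]))
    ys = np.linspace(0.0, ey, 60)
    road = LineString(np.column_stack([0.65 * ex + _meander(rng, 60, 0.12 * ex), ys]))

    river_dist = distance_raster([river], grid)
    road_dist = distance_raster([road], grid)

    lp = (
        betas.ndvi * _zscore(ndvi.data)
        + betas.dem * _zscore(dem.data)
        - betas.river * _zscore(river_dist.data)
        - betas.road * _zscore(road_dist.data)
    )
    intensity = np.exp(lp)
    intensity *= betas.mean_intensity / intensity.mean()

    return Environment(
        dem=dem,
        ndvi=ndvi,
        river=river,
        road=road,
        river_dist=river_dist,
        road_dist=road_dist,
        intensity=grid.like(intensity),
        betas=betas,
        frame=LocalFrame(anchor_lat, anchor_lon),
    )


def sample_counts(env: Environment, seed: int = 0) -> Raster:
    """Draw a Poisson fix-count raster from the expected intensity."""
    rng = np.random.default_rng(seed)
    return env.intensity.like(rng.poisson(env.intensity.data).astype(float))
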
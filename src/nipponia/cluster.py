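"""Density-based clustering of roost sites with silhouette/noise tuning.

DBSCAN is implemented directly (no library call): a point is a core point
when at least ``min_samples`` points — itself included — lie within
``eps`` metres (great-circle); clusters are maximal density-connected
sets grown from core points; everything else is noise (label −1).
Border points reachable from several clusters are assigned to the first
core point that reaches them in the fixed input scan order — the
documented deterministic tie rule.

Parameter choice follows a constrained lexicographic objective: among
grid combinations whose noise ratio stays under a cap and which produce
at least two clusters, pick the one with the highest silhouette
coefficient, breaking ties by lower noise ratio, then smaller eps.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np
import pandas as pd

from .geo import EARTH_RADIUS_M, haversine_distance


@dataclass(frozen=True)
class ClusterParams:
    eps: float
    min_samples: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be at least 1")


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-point integer label, −1 = noise
    n_clusters: int
    silhouette: float | None    # None when fewer than 2 clusters
    noise_ratio: float
    params: ClusterParams


class TuningError(RuntimeError):
    """Raised when no grid combination satisfies the tuning constraints."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


def pairwise_haversine(points: np.ndarray, radius: float = EARTH_RADIUS_M) -> np.ndarray:
    """Full (n, n) great-circle distance matrix for (lat, lon) rows."""
    lat = points[:, 0]
    lon = points[:, 1]
    return np.atleast_2d(
        haversine_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :], radius=radius)
    )


def dbscan(
    points: np.ndarray,
    params: ClusterParams,
    radius: float = EARTH_RADIUS_M,
    distances: np.ndarray | None = None,
) -> ClusterResult:
    """Density-based clustering of (lat, lon) points with noise marking.

    ``distances`` may supply a precomputed matrix (reused during tuning).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("need at least one point")
    D = pairwise_haversine(points, radius) if distances is None else distances
    within = D <= params.eps
    core = within.sum(axis=1) >= params.min_samples  # neighbourhood includes self
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for seed_idx in range(n):
        if not core[seed_idx] or labels[seed_idx] != -1:
            continue
        # breadth-first growth from this core point, in scan order
        labels[seed_idx] = cluster
        queue = deque([seed_idx])
        while queue:
            p = queue.popleft()
            if not core[p]:
                continue  # border point: reachable but does not expand
            for q in np.flatnonzero(within[p]):
                if labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    n_clusters = cluster
    noise_ratio = float(np.mean(labels == -1))
    sil = None
    if n_clusters >= 2:
        sil = silhouette_coefficient(points, labels, radius=radius, distances=D)
    return ClusterResult(labels, n_clusters, sil, noise_ratio, params)


def silhouette_coefficient(
    points: np.ndarray,
    labels: np.ndarray,
    radius: float = EARTH_RADIUS_M,
    distances: np.ndarray | None = None,
) -> float:
    """Mean silhouette s(i) = (b−a)/max(a, b) over non-noise points.

    a(i) is the mean great-circle distance to the other members of i's
    cluster, b(i) the smallest mean distance to any other cluster.
    Noise points (label −1) are excluded; members of singleton clusters
    contribute s(i) = 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0
    uniq = np.unique(labels[keep])
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters (noise excluded)")
    D = pairwise_haversine(points, radius) if distances is None else distances
    scores = []
    for i in np.flatnonzero(keep):
        own = labels[i]
        own_members = np.flatnonzero((labels == own) & (np.arange(len(labels)) != i))
        if len(own_members) == 0:
            scores.append(0.0)  # singleton cluster
            continue
        a = D[i, own_members].mean()
        b = min(D[i, labels == other].mean() for other in uniq if other != own)
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def tune_parameters(
    points: np.ndarray,
    eps_grid: list[float] | None = None,
    min_samples_grid: list[int] | None = None,
    noise_cap: float = 0.2,
    radius: float = EARTH_RADIUS_M,
) -> tuple[ClusterParams, ClusterResult, pd.DataFrame]:
    """Grid-search (eps, min_samples) by silhouette under a noise cap.

    Every combination is evaluated; the report (one row per combination,
    columns eps, min_samples, n_clusters, silhouette, noise_ratio) is
    returned for audit.  Raises :class:`TuningError` (carrying the report)
    when no combination yields at least two clusters within the cap.
    """
    eps_grid = eps_grid if eps_grid is not None else [100.0, 200.0, 500.0, 1000.0, 2000.0]
    min_samples_grid = min_samples_grid if min_samples_grid is not None else [3, 4, 5, 10]
    if not eps_grid or not min_samples_grid:
        raise ValueError("parameter grids must be non-empty")
    points = np.asarray(points, dtype=float)
    D = pairwise_haversine(points, radius)
    rows = []
    results: dict[tuple[float, int], ClusterResult] = {}
    for eps in eps_grid:
        for ms in min_samples_grid:
            params = ClusterParams(eps=float(eps), min_samples=int(ms))
            res = dbscan(points, params, radius=radius, distances=D)
            results[(params.eps, params.min_samples)] = res
            rows.append(
                {
                    "eps": params.eps,
                    "min_samples": params.min_samples,
                    "n_clusters": res.n_clusters,
                    "silhouette": res.silhouette if res.silhouette is not None else np.nan,
                    "noise_ratio": res.noise_ratio,
                }
            )
    report = pd.DataFrame(rows)
    ok = report[(report["n_clusters"] >= 2) & (report["noise_ratio"] <= noise_cap)]
    if len(ok) == 0:
        raise TuningError(
            "no (eps, min_samples) combination produced >= 2 clusters "
            f"with noise ratio <= {noise_cap}",
            report,
        )
    best = ok.sort_values(
        ["silhouette", "noise_ratio", "eps"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    params = ClusterParams(eps=float(best["eps"]), min_samples=int(best["min_samples"]))
    return params, results[(params.eps, params.min_samples)], report
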
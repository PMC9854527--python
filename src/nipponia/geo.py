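"""Geodesic distance and regression metrics shared by every pipeline stage.

All distances are great-circle (haversine) distances on a sphere of
configurable radius; the default radius is the mean Earth radius
EARTH_RADIUS_M = 6,371,000 m.  Coordinates are geographic degrees.
Timestamps throughout the package are naive local civil time: the diurnal
hour rules used downstream are defined in the animals' local day, so no
timezone conversion is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_M: float = 6_371_000.0

#: canonical column order of the trajectory CSV dialect
FIX_COLUMNS = ["individual_id", "timestamp", "lat", "lon", "imputed"]


@dataclass(frozen=True)
class EvalMetrics:
    """Regression evaluation bundle: R², RMSE, MAE and explained variance.

    ``r2`` and ``explained_variance`` are unitless and bounded above by 1;
    ``rmse`` and ``mae`` carry the units of the response, with
    ``rmse >= mae >= 0``.
    """

    r2: float
    rmse: float
    mae: float
    explained_variance: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "explained_variance": self.explained_variance,
        }


def _validate_coords(lat, lon) -> tuple[np.ndarray, np.ndarray]:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    return lat, lon


def haversine_distance(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between two points (vectorized).

    D = 2 r asin( sqrt( sin²(Δφ/2) + cos φ1 cos φ2 sin²(Δλ/2) ) )

    Parameters are degrees; ``radius`` is the sphere radius in metres.
    Raises ``ValueError`` on out-of-range coordinates or non-positive radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lat1, lon1 = _validate_coords(lat1, lon1)
    lat2, lon2 = _validate_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative / >1 rounding at antipodes
    d = 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.isscalar(lat1) or d.ndim == 0:
        return float(d)
    return d


def mse(y, yhat) -> float:
    """Mean squared error (1/m)·Σ(y−ŷ)²; inputs must be equal-length, m ≥ 1."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("mse of empty input is undefined")
    return float(np.mean((y - yhat) ** 2))


def regression_metrics(y, yhat) -> EvalMetrics:
    """R², RMSE, MAE and explained variance of predictions ``yhat`` for ``y``.

    R²   = 1 − Σ(ŷ−y)² / Σ(ȳ−y)²
    EV   = 1 − Var(y−ŷ) / Var(y)      (population variances)

    Requires n ≥ 2 and non-constant ``y`` (a constant response makes the R²
    denominator zero); raises ``ValueError`` otherwise — fail-fast rather
    than returning NaN.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant y")
    resid = y - yhat
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    ev = 1.0 - float(np.var(resid)) / float(np.var(y))
    return EvalMetrics(
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        explained_variance=ev,
    )


# ---------------------------------------------------------------------------
# trajectory CSV dialect


def validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Check the fix-table contract and return the frame (sorted, typed).

    Contract: columns ``individual_id,timestamp,lat,lon,imputed``;
    coordinates in range; timestamps strictly increasing per individual.
    """
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table missing columns: {missing}")
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    out["imputed"] = out["imputed"].astype(bool)
    _validate_coords(out["lat"].to_numpy(), out["lon"].to_numpy())
    out = out.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    for ind, grp in out.groupby("individual_id", sort=False):
        if grp["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps for individual {ind!r}")
    return out


def read_fixes(path) -> pd.DataFrame:
    """Read a trajectory CSV (``individual_id,timestamp,lat,lon,imputed``)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return validate_fixes(df)


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table in the canonical CSV dialect (ISO-8601 timestamps)."""
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
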
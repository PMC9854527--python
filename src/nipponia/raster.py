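"""Minimal gridded-raster container, local metric projection and vector IO.

The analysis works in a local planar frame: east/north metres around an
anchor latitude/longitude, converted with the equirectangular
approximation (exact enough for study extents well under 100 km).  Rasters
are stored row-major with row 0 at the *southern* edge (y increasing with
row index) and serialized as ESRI ASCII grids, which flip to the
north-up row order that format requires.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, mapping

from .geo import EARTH_RADIUS_M


@dataclass(frozen=True)
class LocalFrame:
    """Equirectangular mapping between (lat, lon) degrees and (x, y) metres.

    ``(anchor_lat, anchor_lon)`` maps to (0, 0); x is east, y is north.
    """

    anchor_lat: float
    anchor_lon: float
    radius: float = EARTH_RADIUS_M

    @property
    def _m_per_deg(self) -> float:
        return self.radius * math.pi / 180.0

    def to_xy(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        y = (lat - self.anchor_lat) * self._m_per_deg
        x = (lon - self.anchor_lon) * self._m_per_deg * math.cos(math.radians(self.anchor_lat))
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.anchor_lat + y / self._m_per_deg
        lon = self.anchor_lon + x / (self._m_per_deg * math.cos(math.radians(self.anchor_lat)))
        return lat, lon


@dataclass
class Raster:
    """2-D grid of cell values with a square-cell planar geotransform.

    ``data[i, j]`` covers the half-open cell
    [x0 + j·s, x0 + (j+1)·s) × [y0 + i·s, y0 + (i+1)·s)  with s = cell_size.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 200.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays of shape equal to the raster."""
        ny, nx = self.data.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the half-open cell containing each (x, y)."""
        i = np.floor((np.asarray(y, float) - self.y0) / self.cell_size).astype(int)
        j = np.floor((np.asarray(x, float) - self.x0) / self.cell_size).astype(int)
        return i, j

    def sample_nearest(self, x, y) -> np.ndarray:
        """Nearest-neighbour sample at planar coordinates, clamped to edges."""
        i, j = self.index_of(x, y)
        ny, nx = self.data.shape
        i = np.clip(i, 0, ny - 1)
        j = np.clip(j, 0, nx - 1)
        return self.data[i, j]

    def like(self, data: np.ndarray) -> "Raster":
        """A new raster sharing this grid's geotransform."""
        return Raster(data, self.x0, self.y0, self.cell_size, self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Serialize as an ESRI ASCII grid (plain text, north-up row order)."""
    ny, nx = raster.shape
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {raster.x0:.6f}\n"
        f"yllcorner {raster.y0:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    return Raster(
        data,
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        cell_size=hdr["cellsize"],
        nodata=hdr.get("nodata_value", -9999.0),
    )


def rasterize_lines(lines: list[LineString], grid: Raster) -> np.ndarray:
    """Boolean mask of grid cells touched by any polyline.

    Lines are densified at cell_size/4 steps; adequate for distance
    transforms at the analysis resolution.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    step = grid.cell_size / 4.0
    ny, nx = grid.shape
    for line in lines:
        n = max(int(math.ceil(line.length / step)), 1)
        pts = [line.interpolate(d) for d in np.linspace(0.0, line.length, n + 1)]
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        i, j = grid.index_of(xs, ys)
        ok = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
        mask[i[ok], j[ok]] = True
    return mask


def distance_raster(lines: list[LineString], grid: Raster) -> Raster:
    """Euclidean distance (metres) from each cell to the nearest polyline.

    Distance transform of the rasterized polyline mask; cells crossed by a
    line get distance 0.
    """
    mask = rasterize_lines(lines, grid)
    if not mask.any():
        raise ValueError("no polyline intersects the grid extent")
    dist = ndimage.distance_transform_edt(~mask) * grid.cell_size
    return grid.like(dist)


def lines_to_geojson(lines: dict[str, LineString], frame: LocalFrame, path) -> None:
    """Write named planar polylines as a GeoJSON FeatureCollection (lat/lon)."""
    feats = []
    for name, line in lines.items():
        xs, ys = zip(*line.coords)
        lat, lon = frame.to_latlon(np.array(xs), np.array(ys))
        geom = mapping(LineString(zip(lon, lat)))
        feats.append({"type": "Feature", "properties": {"name": name}, "geometry": geom})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def points_to_geojson(records: list[dict], path) -> None:
    """Write point records (each with 'lat'/'lon' plus properties) as GeoJSON."""
    feats = []
    for rec in records:
        props = {k: v for k, v in rec.items() if k not in ("lat", "lon")}
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {"type": "Point", "coordinates": [rec["lon"], rec["lat"]]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1, default=str)
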
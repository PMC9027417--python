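"""Geographic analysis grid.

The study area is tiled with square cells in WGS84 decimal degrees (no
projection is applied; a 0.5 degree cell spans half a degree of longitude
and latitude regardless of latitude).  Cells are indexed row-major from the
south-west corner.  Cell intervals are half-open ``[min, max)`` except on
the grid's outermost north/east edge, which is closed so every point of the
extent maps to exactly one cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "GridSpec",
    "make_grid",
    "assign_cell",
    "assign_cells",
    "nominal_cell_area_km2",
]

#: conventional km per degree used for nominal areas (55 km per half degree)
KM_PER_DEGREE = 110.0

_EPS = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with row-major integer cell ids.

    Row 0 is the southernmost row; cell id ``row * n_cols + col``.
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    resolution: float
    n_rows: int
    n_cols: int

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.lon_min, self.lat_min, self.lon_max, self.lat_max)

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min - _EPS <= lon <= self.lon_max + _EPS
            and self.lat_min - _EPS <= lat <= self.lat_max + _EPS
        )

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        if not 0 <= cell_id < self.n_cells:
            raise IndexError(f"cell_id {cell_id} outside 0..{self.n_cells - 1}")
        return divmod(cell_id, self.n_cols)

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row, col) = ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell's box."""
        row, col = self.rowcol(cell_id)
        lon0 = self.lon_min + col * self.resolution
        lat0 = self.lat_min + row * self.resolution
        return (lon0, lat0, lon0 + self.resolution, lat0 + self.resolution)

    def cell_center(self, cell_id: int) -> tuple[float, float]:
        lon0, lat0, lon1, lat1 = self.cell_bounds(cell_id)
        return ((lon0 + lon1) / 2.0, (lat0 + lat1) / 2.0)

    # -- serialization -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lat_min": self.lat_min,
            "lon_max": self.lon_max,
            "lat_max": self.lat_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "GridSpec":
        return make_grid(
            (cfg["lon_min"], cfg["lat_min"], cfg["lon_max"], cfg["lat_max"]),
            cfg["resolution"],
        )

    def cells_geojson(self, cell_ids=None, properties=None) -> dict:
        """Cell boxes as a GeoJSON FeatureCollection with a cell_id property.

        ``properties`` maps cell_id -> extra property dict.
        """
        if cell_ids is None:
            cell_ids = range(self.n_cells)
        features = []
        for cid in cell_ids:
            lon0, lat0, lon1, lat1 = self.cell_bounds(cid)
            props = {"cell_id": int(cid)}
            if properties and cid in properties:
                props.update(properties[cid])
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [
                                [lon0, lat0],
                                [lon1, lat0],
                                [lon1, lat1],
                                [lon0, lat1],
                                [lon0, lat0],
                            ]
                        ],
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path, cell_ids=None, properties=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.cells_geojson(cell_ids, properties), fh)


def make_grid(extent: tuple[float, float, float, float], resolution: float = 0.5) -> GridSpec:
    """Build a grid tiling ``extent``, expanding outward to whole cells.

    Bounds are snapped to the global lattice of multiples of ``resolution``
    (minima floored, maxima ceiled) so the returned grid tiles the expanded
    extent exactly.
    """
    lon_min, lat_min, lon_max, lat_max = extent
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError(f"inverted or empty extent {extent}")
    lo_c = math.floor(lon_min / resolution + _EPS) * resolution
    la_c = math.floor(lat_min / resolution + _EPS) * resolution
    lo_x = math.ceil(lon_max / resolution - _EPS) * resolution
    la_x = math.ceil(lat_max / resolution - _EPS) * resolution
    n_cols = int(round((lo_x - lo_c) / resolution))
    n_rows = int(round((la_x - la_c) / resolution))
    return GridSpec(lo_c, la_c, lo_x, la_x, resolution, n_rows, n_cols)


def assign_cell(lon: float, lat: float, grid: GridSpec) -> int:
    """Map one point to its cell id (half-open boxes, closed at the max edge)."""
    if not grid.contains(lon, lat):
        raise ValueError(f"point ({lon}, {lat}) outside grid extent {grid.extent}")
    col = int(math.floor((lon - grid.lon_min) / grid.resolution + _EPS))
    row = int(math.floor((lat - grid.lat_min) / grid.resolution + _EPS))
    col = min(col, grid.n_cols - 1)
    row = min(row, grid.n_rows - 1)
    return grid.cell_id(row, col)


def assign_cells(lons, lats, grid: GridSpec):
    """Vectorized :func:`assign_cell` for equal-length coordinate arrays."""
    import numpy as np

    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    inside = (
        (lons >= grid.lon_min - _EPS)
        & (lons <= grid.lon_max + _EPS)
        & (lats >= grid.lat_min - _EPS)
        & (lats <= grid.lat_max + _EPS)
    )
    if not inside.all():
        bad = np.argmax(~inside)
        raise ValueError(
            f"point ({lons[bad]}, {lats[bad]}) outside grid extent {grid.extent}"
        )
    col = np.floor((lons - grid.lon_min) / grid.resolution + _EPS).astype(np.int64)
    row = np.floor((lats - grid.lat_min) / grid.resolution + _EPS).astype(np.int64)
    np.clip(col, 0, grid.n_cols - 1, out=col)
    np.clip(row, 0, grid.n_rows - 1, out=row)
    return row * grid.n_cols + col


def nominal_cell_area_km2(grid: GridSpec, km_per_degree: float = KM_PER_DEGREE) -> float:
    """Nominal area of one cell, ``(resolution * km_per_degree)**2``.

    With the default 110 km/degree convention a 0.5 degree cell covers
    55 km x 55 km = 3025 km^2.
    """
    if km_per_degree <= 0:
        raise ValueError(f"km_per_degree must be positive, got {km_per_degree}")
    return (grid.resolution * km_per_degree) ** 2
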
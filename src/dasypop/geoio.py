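"""Raster/vector I/O, grid alignment, and polygon rasterization.

The analysis grid is a north-up regular lattice: row 0 is the northern edge,
cell indices are 0-based, and a cell (r, c) covers the half-open box
``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]``
where ``s`` is the cell size.  Two grids are aligned iff origin, cell size
and dimensions are identical.

Coordinate reference systems are identified by a string: ``"EPSG:4326"``
(geographic degrees, the native frame of real settlement and census
products) or any id starting with ``"planar"`` (projected metres, used by
the synthetic-country generator so cell areas are exact).

Rasters are stored as single-band GeoTIFFs via :mod:`tifffile`; the grid
definition, nodata value and free-form metadata ride in the ImageDescription
tag as JSON, and standard GeoTIFF pixel-scale/tiepoint tags are written so
generic GIS software can place the file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from . import _proj
from .errors import (
    AlignmentError,
    EmptyZoneError,
    GeometryError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "GridSpec",
    "Raster",
    "CensusUnitSet",
    "ZoneRaster",
    "read_units",
    "write_units",
    "rasterize_units",
    "read_raster",
    "write_population_raster",
    "write_raster",
    "geometry_area_km2",
]

ZONE_NODATA = -1

# GeoTIFF tags for georeferencing
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


@dataclass(frozen=True)
class GridSpec:
    """Definition of the common analysis grid.

    ``origin_x``/``origin_y`` locate the *outer corner* of cell (0, 0) —
    i.e. the north-west corner of the grid.  ``cell_size`` is in the units
    of ``crs_id`` (degrees for geographic, metres for planar); the nominal
    analysis resolution is 3 arc-seconds, roughly 100 m at the equator.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def aligned_with(self, other: "GridSpec") -> bool:
        return (
            math.isclose(self.origin_x, other.origin_x, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
            and self.shape == other.shape
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def col_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def row_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_size_m(self) -> float:
        """Cell edge length in metres (approximate for geographic grids)."""
        if _proj.is_planar(self.crs_id):
            return self.cell_size
        # metres per degree of longitude at the grid's mid latitude
        lat_mid = self.origin_y - 0.5 * self.n_rows * self.cell_size
        return self.cell_size * 111320.0 * max(math.cos(math.radians(lat_mid)), 0.2)

    def to_dict(self) -> dict[str, Any]:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs_id": self.crs_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GridSpec":
        return cls(
            origin_x=float(d["origin_x"]),
            origin_y=float(d["origin_y"]),
            cell_size=float(d["cell_size"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            crs_id=str(d.get("crs_id", "EPSG:4326")),
        )


@dataclass
class Raster:
    """A single-band raster bound to a :class:`GridSpec`.

    ``nodata`` is the sentinel marking cells outside the analysis mask; it
    defaults to NaN for float data.  All statistics in this package exclude
    nodata cells.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Values as float64 with nodata replaced by NaN."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.valid] = np.nan
        return out

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata)


@dataclass
class ZoneRaster:
    """Integer unit index per cell; ``ZONE_NODATA`` outside all units."""

    grid: GridSpec
    values: np.ndarray  # int32
    unit_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        if self.values.shape != self.grid.shape:
            raise ValidationError("zone raster shape mismatch")

    @property
    def valid(self) -> np.ndarray:
        return self.values != ZONE_NODATA

    def cell_counts(self) -> np.ndarray:
        """Number of cells claimed by each unit, indexed like ``unit_ids``."""
        v = self.values[self.valid]
        return np.bincount(v, minlength=len(self.unit_ids))


class CensusUnitSet:
    """A polygon partition with per-unit population counts and areas.

    The disaggregation source (aggregated level) and the validation truth
    (finest level) are both instances of this class.  Geometries are shapely
    polygons/multipolygons forming a partition: pairwise interior-disjoint.
    """

    def __init__(
        self,
        unit_ids: Sequence,
        geometries: Sequence[BaseGeometry],
        populations: Sequence[float],
        areas_km2: Sequence[float] | None = None,
        level_tag: str = "",
        crs_id: str = "EPSG:4326",
    ) -> None:
        n = len(unit_ids)
        if not (len(geometries) == len(populations) == n):
            raise ValidationError("unit_ids, geometries, populations length mismatch")
        if len(set(unit_ids)) != n:
            raise ValidationError("unit_ids must be unique")
        self.unit_ids = list(unit_ids)
        self.geometries = list(geometries)
        self.populations = np.asarray(populations, dtype=np.float64)
        self.level_tag = level_tag
        self.crs_id = crs_id
        for uid, g in zip(self.unit_ids, self.geometries):
            if g.geom_type not in ("Polygon", "MultiPolygon"):
                raise GeometryError(f"unit {uid!r}: geometry is {g.geom_type}, not polygonal")
        if np.any(self.populations < 0):
            bad = [u for u, p in zip(self.unit_ids, self.populations) if p < 0]
            raise ValidationError(f"negative population for units {bad}")
        if areas_km2 is None:
            areas_km2 = [geometry_area_km2(g, crs_id) for g in self.geometries]
        self.areas_km2 = np.asarray(areas_km2, dtype=np.float64)
        if np.any(self.areas_km2 <= 0):
            raise ValidationError("all unit areas must be positive")

    def __len__(self) -> int:
        return len(self.unit_ids)

    def __repr__(self) -> str:
        return (
            f"CensusUnitSet(n={len(self)}, total_pop={self.total_population():.0f},"
            f" level={self.level_tag!r})"
        )

    def total_population(self) -> float:
        return float(self.populations.sum())

    def total_area_km2(self) -> float:
        return float(self.areas_km2.sum())

    def index_of(self, unit_id) -> int:
        return self.unit_ids.index(unit_id)

    def subset(self, indices: Sequence[int]) -> "CensusUnitSet":
        return CensusUnitSet(
            [self.unit_ids[i] for i in indices],
            [self.geometries[i] for i in indices],
            self.populations[list(indices)],
            self.areas_km2[list(indices)],
            level_tag=self.level_tag,
            crs_id=self.crs_id,
        )


def geometry_area_km2(geom: BaseGeometry, crs_id: str) -> float:
    """Area of a polygon in km².

    Planar CRS coordinates are metres, so area is direct.  Geographic
    coordinates are projected to the UTM zone of the geometry centroid
    first, matching the region-specific UTM convention used for all metric
    computations in this pipeline.
    """
    if _proj.is_planar(crs_id):
        return geom.area / 1e6
    zone = _proj.utm_zone_of(geom.centroid.x)
    total = 0.0
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        ext = shapely.Polygon(
            _proj.project_ring(poly.exterior.coords, zone),
            [_proj.project_ring(r.coords, zone) for r in poly.interiors],
        )
        total += ext.area
    return total / 1e6


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_units(
    path: str | Path,
    pop_field: str = "pop",
    id_field: str = "unit_id",
    level_field: str = "level",
    area_field: str = "area_km2",
    crs_id: str | None = None,
) -> CensusUnitSet:
    """Read a census unit set from a GeoJSON FeatureCollection.

    Attribute names are configurable; ``area_km2`` is computed from the
    geometry (UTM-projected for geographic data) when the attribute is
    absent.  A missing population attribute raises :class:`SchemaError`;
    non-polygonal features raise :class:`GeometryError`.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features")
    if feats is None:
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    if crs_id is None:
        crs_id = doc.get("crs_id", "EPSG:4326")

    ids, geoms, pops, areas, levels = [], [], [], [], []
    have_area = True
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if pop_field not in props:
            raise SchemaError(f"feature {i}: missing population attribute {pop_field!r}")
        geom = geom_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"feature {i}: {geom.geom_type} is not polygonal")
        ids.append(props.get(id_field, i))
        geoms.append(geom)
        pops.append(float(props[pop_field]))
        levels.append(props.get(level_field, ""))
        if area_field in props:
            areas.append(float(props[area_field]))
        else:
            have_area = False
    level_tag = levels[0] if levels and all(l == levels[0] for l in levels) else ""
    return CensusUnitSet(
        ids,
        geoms,
        pops,
        areas if have_area else None,
        level_tag=level_tag,
        crs_id=crs_id,
    )


def write_units(
    units: CensusUnitSet,
    path: str | Path,
    pop_field: str = "pop",
    id_field: str = "unit_id",
) -> None:
    """Write a unit set as GeoJSON (with a ``crs_id`` foreign member)."""
    feats = []
    for i in range(len(units)):
        feats.append(
            {
                "type": "Feature",
                "geometry": geom_mapping(units.geometries[i]),
                "properties": {
                    id_field: units.unit_ids[i],
                    pop_field: units.populations[i],
                    "area_km2": units.areas_km2[i],
                    "level": units.level_tag,
                },
            }
        )
    doc = {"type": "FeatureCollection", "crs_id": units.crs_id, "features": feats}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_units(units: CensusUnitSet, grid: GridSpec) -> ZoneRaster:
    """Assign each grid cell to the unit containing its center.

    Cell-center rule: a cell belongs to the unit whose polygon covers the
    cell's center point.  Centers lying exactly on a shared boundary are
    claimed by the unit with the lowest index (deterministic first-wins
    tie-break).  Cells outside every unit are nodata.
    """
    zones = np.full(grid.shape, ZONE_NODATA, dtype=np.int32)
    xs = grid.col_centers()
    ys = grid.row_centers()
    s = grid.cell_size
    for idx, geom in enumerate(units.geometries):
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(int(math.floor((minx - grid.origin_x) / s - 0.5)), 0)
        c1 = min(int(math.ceil((maxx - grid.origin_x) / s + 0.5)), grid.n_cols)
        r0 = max(int(math.floor((grid.origin_y - maxy) / s - 0.5)), 0)
        r1 = min(int(math.ceil((grid.origin_y - miny) / s + 0.5)), grid.n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        hit = shapely.intersects_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
        window = zones[r0:r1, c0:c1]
        assign = hit & (window == ZONE_NODATA)
        window[assign] = idx
    if not np.any(zones != ZONE_NODATA):
        raise EmptyZoneError("no grid cell center falls inside any unit")
    return ZoneRaster(grid, zones, list(units.unit_ids))


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF)
# ---------------------------------------------------------------------------

def write_raster(
    raster: Raster,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
    dtype=None,
) -> None:
    """Write a raster as a single-band GeoTIFF.

    Grid definition, nodata and user metadata are stored as JSON in the
    ImageDescription tag; GeoTIFF pixel-scale and tiepoint tags are also
    written.  Values round-trip bit-identically through :func:`read_raster`.
    """
    values = raster.values if dtype is None else raster.values.astype(dtype)
    desc = json.dumps(
        {
            "grid": raster.grid.to_dict(),
            "nodata": None
            if isinstance(raster.nodata, float) and math.isnan(raster.nodata)
            else raster.nodata,
            "metadata": dict(metadata or {}),
        }
    )
    s = raster.grid.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, raster.grid.origin_x, raster.grid.origin_y, 0.0),
        ),
    ]
    tifffile.imwrite(str(path), values, description=desc, extratags=extratags)


def write_population_raster(
    pop: Raster, path: str | Path, metadata: Mapping[str, Any] | None = None
) -> None:
    """Write a people-per-pixel raster (float64 band) with model metadata."""
    write_raster(pop, path, metadata=metadata, dtype=np.float64)


def read_raster(path: str | Path) -> tuple[Raster, dict[str, Any]]:
    """Read a GeoTIFF written by :func:`write_raster`.

    Returns the raster and the user metadata dict stored at write time.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise SchemaError(f"{path}: missing grid metadata")
        info = json.loads(desc.value)
    grid = GridSpec.from_dict(info["grid"])
    nodata = info.get("nodata")
    nodata = float("nan") if nodata is None else nodata
    return Raster(grid, values, nodata), info.get("metadata", {})
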
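"""Covariate stack assembly and zonal statistics.

All covariate layers — land-cover class masks, distance-to-edge surfaces,
lights, climate, terrain — must share the analysis grid and a common
nodata footprint before model fitting.  The footprint is an analysis mask
built from the country boundary buffered outward by 8 km (so the stacked
extents of all products coincide even where borders disagree) minus water
cells from the land-cover product (population is never placed on water).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from . import _proj
from .builtarea import MASK_NODATA, BuiltMask
from .errors import AlignmentError, EmptyZoneError, ValidationError
from .geoio import GridSpec, Raster, ZoneRaster

__all__ = [
    "CovariateStack",
    "ZonalTable",
    "split_landcover",
    "build_analysis_mask",
    "assemble_stack",
    "zonal_stat",
]


@dataclass
class CovariateStack:
    """Named, aligned covariate layers with one shared nodata footprint."""

    layers: dict[str, Raster]
    grid: GridSpec
    mask: Raster  # 1 = analysis cell, 0/nodata = excluded

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid(self) -> np.ndarray:
        return (self.mask.values == 1) & self.mask.valid

    def matrix(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells, n_layers) design matrix and the valid-cell mask."""
        names = names or self.names
        valid = self.valid
        cols = [self.layers[n].values[valid].astype(np.float64) for n in names]
        return np.column_stack(cols), valid


@dataclass
class ZonalTable:
    """Per-unit statistic of a raster: one row per unit in the zone raster."""

    table: pd.DataFrame  # index: unit_id; columns: layer names
    stat_tag: str
    empty_units: list = field(default_factory=list)  # units with 0 valid cells


def split_landcover(lc: Raster, classes) -> list[BuiltMask]:
    """One binary mask per land-cover class.

    A class absent from the raster yields an all-zero mask with a warning.
    If the class list is exhaustive the masks partition the valid domain.
    """
    classes = list(classes)
    if not classes:
        raise ValidationError("empty class list")
    valid = lc.valid
    present = set(np.unique(lc.values[valid]).tolist())
    masks = []
    for cls in classes:
        if cls not in present:
            warnings.warn(f"land-cover class {cls} absent from raster", stacklevel=2)
        vals = np.where(valid & (lc.values == cls), 1, 0).astype(np.uint8)
        vals[~valid] = MASK_NODATA
        masks.append(
            BuiltMask(
                Raster(lc.grid, vals, nodata=MASK_NODATA),
                source_tag=f"lc_{cls}",
            )
        )
    return masks


def _buffer_distance(buffer_km: float, crs_id: str) -> float:
    if _proj.is_planar(crs_id):
        return buffer_km * 1000.0
    return buffer_km / 111.32  # degrees, adequate for a coarse over-buffer


def build_analysis_mask(
    lc: Raster,
    boundary: BaseGeometry,
    buffer_km: float = 8.0,
    water_classes=(210,),
) -> Raster:
    """Analysis mask: inside the buffered boundary and not water.

    A cell is valid iff its center lies within the country boundary
    buffered outward by ``buffer_km`` AND its land-cover class is not a
    water class.  The outward buffer deliberately over-estimates the
    border so every stacked covariate shares an identical extent.
    """
    grid = lc.grid
    buffered = boundary.buffer(_buffer_distance(buffer_km, grid.crs_id))
    xs = grid.col_centers()
    ys = grid.row_centers()
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(buffered, gx.ravel(), gy.ravel()).reshape(grid.shape)
    water = np.isin(lc.values, list(water_classes)) & lc.valid
    valid = inside & ~water
    if not valid.any():
        raise ValidationError("buffered boundary and water exclusion leave no cells")
    return Raster(grid, valid.astype(np.uint8), nodata=MASK_NODATA)


def _crop_to(layer: Raster, grid: GridSpec) -> Raster:
    """Crop/pad a layer on the same lattice to the target grid window."""
    src = layer.grid
    if src.aligned_with(grid):
        return layer
    if not math.isclose(src.cell_size, grid.cell_size, rel_tol=1e-12):
        raise AlignmentError("layer cell size differs from target grid")
    dc = (grid.origin_x - src.origin_x) / grid.cell_size
    dr = (src.origin_y - grid.origin_y) / grid.cell_size
    if abs(dc - round(dc)) > 1e-6 or abs(dr - round(dr)) > 1e-6:
        raise AlignmentError("layer lattice is offset from target grid")
    dc, dr = int(round(dc)), int(round(dr))
    out = np.full(grid.shape, np.nan)
    r0, r1 = max(0, -dr), min(grid.n_rows, src.n_rows - dr)
    c0, c1 = max(0, -dc), min(grid.n_cols, src.n_cols - dc)
    if r0 < r1 and c0 < c1:
        vals = layer.masked()
        out[r0:r1, c0:c1] = vals[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return Raster(grid, out)


def assemble_stack(
    layers: dict[str, Raster], grid: GridSpec, mask: Raster
) -> CovariateStack:
    """Align layers to the grid, clip to the mask, harmonize nodata.

    After assembly every layer is float64 on the target grid with NaN at
    exactly the cells excluded by the mask or missing in ANY layer, so the
    nodata footprint is identical across the stack.
    """
    if len(set(layers)) != len(layers):
        raise ValidationError("layer names must be unique")
    if not mask.grid.aligned_with(grid):
        raise AlignmentError("mask not aligned to target grid")
    aligned = {name: _crop_to(lyr, grid).masked() for name, lyr in layers.items()}
    footprint = (mask.values == 1) & mask.valid
    for vals in aligned.values():
        footprint &= ~np.isnan(vals)
    out_layers = {}
    for name, vals in aligned.items():
        v = vals.copy()
        v[~footprint] = np.nan
        if not np.isfinite(v).any():
            raise ValidationError(f"layer {name!r} has zero valid cells after masking")
        out_layers[name] = Raster(grid, v)
    harmonized_mask = Raster(grid, footprint.astype(np.uint8), nodata=MASK_NODATA)
    return CovariateStack(out_layers, grid, harmonized_mask)


def zonal_stat(raster: Raster, zones: ZoneRaster, stat: str = "mean") -> ZonalTable:
    """Per-unit ``mean``, ``sum`` or ``count`` of a raster over zone cells.

    Sums are conservative: the zonal sums over all units add up to the
    global sum over valid zoned cells.  Units with zero valid cells are
    listed in ``empty_units`` and carry NaN.
    """
    if not zones.grid.aligned_with(raster.grid):
        raise AlignmentError("zones not aligned to raster")
    if stat not in ("mean", "sum", "count"):
        raise ValidationError(f"unknown stat {stat!r}")
    n_units = len(zones.unit_ids)
    cell_ok = zones.valid & raster.valid
    z = zones.values[cell_ok]
    v = raster.values[cell_ok].astype(np.float64)
    sums = np.bincount(z, weights=v, minlength=n_units)
    counts = np.bincount(z, minlength=n_units).astype(np.float64)
    if stat == "sum":
        out = sums
    elif stat == "count":
        out = counts
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if stat in ("sum", "count"):
        out = np.where(counts > 0, out, np.nan)
    empty = [uid for uid, c in zip(zones.unit_ids, counts) if c == 0]
    table = pd.DataFrame({"value": out}, index=pd.Index(zones.unit_ids, name="unit_id"))
    return ZonalTable(table, stat, empty)


def zonal_stat_stack(
    stack: CovariateStack, zones: ZoneRaster, stat: str = "mean"
) -> ZonalTable:
    """Zonal statistic of every stack layer; columns are layer names."""
    cols = {}
    empty: list = []
    for name, layer in stack.layers.items():
        zt = zonal_stat(layer, zones, stat)
        cols[name] = zt.table["value"]
        empty = zt.empty_units
    return ZonalTable(pd.DataFrame(cols), stat, empty)
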
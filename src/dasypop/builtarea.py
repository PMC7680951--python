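"""Harmonization of built-settlement products into aligned binary masks.

Settlement layers (WSF, GHSL, HRSL — or synthetic stand-ins) arrive at
heterogeneous native resolutions.  They are binarized, resampled onto the
common ~100 m analysis grid by a presence/non-presence rule (a coarse cell
is built iff ANY overlapping native cell is built), optionally unioned into
a combined layer, and converted to signed distance-to-outer-edge (DTE)
surfaces used as covariates: negative inside built features, positive
outside, in metres on the projected grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, UndefinedDistanceError, ValidationError
from .geoio import GridSpec, Raster

__all__ = [
    "BuiltMask",
    "DistanceSurface",
    "binarize",
    "resample_presence",
    "combine_masks",
    "distance_to_edge",
]

MASK_NODATA = 255  # uint8 sentinel


@dataclass
class BuiltMask:
    """Binary built/not-built raster aligned (after resampling) to the grid."""

    raster: Raster
    source_tag: str = "synthetic"
    native_resolution_note: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.raster.values)
        valid = self.raster.valid
        uniq = np.unique(vals[valid])
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be binary, got {uniq[:5]}")

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid

    @property
    def built(self) -> np.ndarray:
        """Boolean built array (nodata counts as not built)."""
        return (self.raster.values == 1) & self.raster.valid

    def built_count(self) -> int:
        return int(self.built.sum())


@dataclass
class DistanceSurface:
    """Signed Euclidean distance to the feature's outer edge, in metres.

    Negative inside the feature, positive outside; the magnitude at any
    cell is the distance to the nearest cell of the opposite class, so both
    proximity outside and interior depth inside are preserved.
    """

    raster: Raster
    feature_tag: str = ""


def _mask_raster(values: np.ndarray, grid: GridSpec) -> Raster:
    return Raster(grid, values.astype(np.uint8), nodata=MASK_NODATA)


def binarize(
    raster: Raster,
    classes=None,
    threshold: float | None = None,
    source_tag: str = "synthetic",
    note: str = "",
) -> BuiltMask:
    """Turn a categorical or continuous raster into a binary mask.

    Exactly one rule applies: ``classes`` (cell is 1 iff its value is one
    of the listed categories) or ``threshold`` (cell is 1 iff value >=
    threshold).  Nodata is preserved.
    """
    if (classes is None) == (threshold is None):
        raise ValidationError("give exactly one of classes= or threshold=")
    valid = raster.valid
    vals = raster.values
    if classes is not None:
        classes = list(np.atleast_1d(classes))
        present = np.unique(vals[valid])
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValidationError(f"classes {missing} absent from raster")
        hit = np.isin(vals, classes)
    else:
        hit = vals >= threshold
    out = np.where(hit & valid, 1, 0).astype(np.uint8)
    out[~valid] = MASK_NODATA
    return BuiltMask(_mask_raster(out, raster.grid), source_tag, note)


def resample_presence(mask: BuiltMask, target: GridSpec) -> BuiltMask:
    """Resample a binary mask to ``target`` by presence/non-presence.

    A target cell is 1 iff any native cell overlapping it (with positive
    overlap area) is 1, and 0 iff every overlapping native cell is 0;
    target cells touched by no valid native cell are nodata.  The native
    grid must be at least as fine as the target and the extents must
    overlap.  Fine cells partially overlapping a coarse cell count as
    covering it.
    """
    src = mask.grid
    if src.cell_size > target.cell_size * (1 + 1e-9):
        raise ValidationError("native grid must be finer than or equal to target")
    sb, tb = src.bounds, target.bounds
    if sb[2] <= tb[0] or sb[0] >= tb[2] or sb[3] <= tb[1] or sb[1] >= tb[3]:
        raise ValidationError("mask and target extents are disjoint")

    s, t = src.cell_size, target.cell_size
    eps = t * 1e-9
    cols = np.arange(src.n_cols)
    rows = np.arange(src.n_rows)
    # half-open fine-cell intervals mapped to target column/row index ranges
    x_lo = src.origin_x + cols * s
    x_hi = x_lo + s
    c_lo = np.floor((x_lo - target.origin_x + eps) / t).astype(np.int64)
    c_hi = np.floor((x_hi - target.origin_x - eps) / t).astype(np.int64)
    y_hi = src.origin_y - rows * s  # top edge
    y_lo = y_hi - s
    r_lo = np.floor((target.origin_y - y_hi + eps) / t).astype(np.int64)
    r_hi = np.floor((target.origin_y - y_lo - eps) / t).astype(np.int64)

    out = np.full(target.shape, MASK_NODATA, dtype=np.uint8)
    covered = np.zeros(target.shape, dtype=bool)
    built_out = np.zeros(target.shape, dtype=bool)

    valid = mask.raster.valid
    built = mask.built

    # A fine cell spans at most (c_hi - c_lo + 1) target cells per axis;
    # with fine <= coarse that is at most 2, so loop over the few offsets.
    max_dc = int((c_hi - c_lo).max(initial=0))
    max_dr = int((r_hi - r_lo).max(initial=0))
    for src_arr, dst in ((valid, covered), (built, built_out)):
        rr, cc = np.nonzero(src_arr)
        if rr.size == 0:
            continue
        for dr in range(max_dr + 1):
            tr = r_lo[rr] + dr
            ok_r = (tr <= r_hi[rr]) & (tr >= 0) & (tr < target.n_rows)
            for dc in range(max_dc + 1):
                tc = c_lo[cc] + dc
                ok = ok_r & (tc <= c_hi[cc]) & (tc >= 0) & (tc < target.n_cols)
                dst[tr[ok], tc[ok]] = True

    out[covered] = 0
    out[built_out] = 1
    return BuiltMask(
        _mask_raster(out, target),
        mask.source_tag,
        mask.native_resolution_note or f"resampled from {s:g}",
    )


def combine_masks(masks: list[BuiltMask]) -> BuiltMask:
    """Cell-wise union (logical OR) of aligned masks; tagged ``COMBO``.

    Combining the independent settlement products trades more commission
    (false built) for fewer omissions, mirroring the combined built layer
    used alongside the individual products.
    """
    if not masks:
        raise ValidationError("no masks to combine")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.aligned_with(grid):
            raise AlignmentError("masks are not aligned")
    any_built = np.zeros(grid.shape, dtype=bool)
    any_valid = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        any_built |= m.built
        any_valid |= m.raster.valid
    out = np.full(grid.shape, MASK_NODATA, dtype=np.uint8)
    out[any_valid] = 0
    out[any_built] = 1
    return BuiltMask(_mask_raster(out, grid), "COMBO", "union of members")


def distance_to_edge(
    mask: BuiltMask, cell_size_m: float | None = None, feature_tag: str | None = None
) -> DistanceSurface:
    """Signed Euclidean distance-to-outer-edge surface in metres.

    Computed by exact Euclidean distance transform on the (projected,
    fixed-cell-size) grid: for cells outside the feature, distance to the
    nearest built cell; inside, minus the distance to the nearest non-built
    cell.  ``cell_size_m`` defaults to the grid's metric cell size.
    Requires at least one built and one non-built cell.
    """
    if cell_size_m is None:
        cell_size_m = mask.grid.cell_size_m()
    valid = mask.raster.valid
    built = mask.built
    nonbuilt = valid & ~built
    if not built.any() or not nonbuilt.any():
        raise UndefinedDistanceError("mask is uniform; distance to edge undefined")
    # treat nodata as non-built for the transform, then blank it out
    inside = ndimage.distance_transform_edt(built)
    outside = ndimage.distance_transform_edt(~built)
    signed = np.where(built, -inside, outside) * cell_size_m
    signed = signed.astype(np.float64)
    signed[~valid] = np.nan
    return DistanceSurface(
        Raster(mask.grid, signed),
        feature_tag if feature_tag is not None else mask.source_tag,
    )
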
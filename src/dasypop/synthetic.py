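"""Desk-scale synthetic countries with a known generative density model.

Every pipeline stage — aggregation, mask harmonization, covariate stacking,
forest fitting, redistribution, validation — can run end-to-end on data
from this module, with the truth known exactly.

A synthetic country lives on a planar pseudo-projection with fixed 100 m
cells (areas are exact; latitude effects are out of scope) and consists of:

* a settlement truth mask: the union of Poisson-placed Gaussian settlement
  clusters, thresholded to binary;
* degraded settlement variants emulating the error modes of real products
  (cluster omissions, scattered commissions, different native resolutions),
  so presence resampling and mask combination are exercised;
* covariates: signed distance-to-edge surfaces of the settlement variants,
  a night-lights-like layer correlated with settlement proximity, a smooth
  climate-like field, and decoy noise layers;
* a log-linear density field ``log lambda = b0 + b1*DTE_km + b2*lights +
  noise`` (expected people per pixel), with ``b0`` calibrated so the
  country total matches a target mean unit population;
* a contiguous rectangular tessellation into census units whose populations
  are Poisson draws of the per-unit expected totals (realistic integer
  count noise).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .builtarea import (
    MASK_NODATA,
    BuiltMask,
    combine_masks,
    distance_to_edge,
    resample_presence,
)
from .covariates import CovariateStack, assemble_stack, build_analysis_mask
from .errors import ValidationError
from .geoio import CensusUnitSet, GridSpec, Raster, ZoneRaster, rasterize_units

__all__ = [
    "SyntheticCountry",
    "make_tessellation",
    "make_country",
    "degrade_mask",
]

PLANAR_CRS = "planar:synthetic"

LC_CROPLAND = 10
LC_WOODY = 50
LC_URBAN = 190
LC_WATER = 210

# Degradation profiles loosely emulating the three real settlement
# products' error modes and native grids (finer native cells by an integer
# factor; omission of whole settlements; scattered false positives).
VARIANT_PROFILES = {
    "WSF": dict(omission_rate=0.15, commission_rate=0.03, native_cell_factor=3),
    "GHSL": dict(omission_rate=0.25, commission_rate=0.06, native_cell_factor=2),
    "HRSL": dict(omission_rate=0.05, commission_rate=0.01, native_cell_factor=4),
}


@dataclass
class SyntheticCountry:
    """A fully specified synthetic study area; see module docstring."""

    grid: GridSpec
    true_density: Raster  # lambda, expected people per pixel
    built_truth: BuiltMask
    built_variants: dict[str, BuiltMask]  # aligned to grid (incl. COMBO)
    stack: CovariateStack
    finest_units: CensusUnitSet
    finest_zones: ZoneRaster
    boundary: shapely.Polygon
    landcover: Raster
    params: dict = field(default_factory=dict)


def make_tessellation(
    n_units: int,
    grid: GridSpec,
    populations=None,
    level_tag: str = "finest",
) -> CensusUnitSet:
    """Contiguous rectangular tessellation of the grid into ``n_units``.

    The grid is cut into ~sqrt(n) horizontal bands, each band into boxes,
    all edges snapped to cell boundaries, so the units partition the grid
    exactly and every unit claims at least one whole cell.  Works for any
    ``n_units`` (no divisibility requirement).
    """
    if n_units < 3:
        raise ValidationError("need at least 3 units")
    rows, cols = grid.n_rows, grid.n_cols
    k = max(1, min(rows, round(math.sqrt(n_units))))
    per_band = [n_units // k + (1 if b < n_units % k else 0) for b in range(k)]
    if max(per_band) > cols:
        raise ValidationError(
            f"grid {rows}x{cols} too small for {n_units} units ({max(per_band)} per band)"
        )
    band_rows = [rows // k + (1 if b < rows % k else 0) for b in range(k)]

    s = grid.cell_size
    x0, y0 = grid.origin_x, grid.origin_y
    geoms, ids = [], []
    r_top = 0
    for b in range(k):
        r_bot = r_top + band_rows[b]
        m = per_band[b]
        widths = [cols // m + (1 if c < cols % m else 0) for c in range(m)]
        c_left = 0
        for w in widths:
            c_right = c_left + w
            geoms.append(
                shapely.box(
                    x0 + c_left * s, y0 - r_bot * s, x0 + c_right * s, y0 - r_top * s
                )
            )
            ids.append(len(ids))
            c_left = c_right
        r_top = r_bot
    if populations is None:
        populations = np.ones(n_units)
    return CensusUnitSet(ids, geoms, populations, level_tag=level_tag, crs_id=PLANAR_CRS)


def _paint_clusters(shape, centers, sigmas, amps) -> np.ndarray:
    """Sum of Gaussian bumps, each painted in a local window."""
    fld = np.zeros(shape)
    n_rows, n_cols = shape
    for (cr, cc), sig, amp in zip(centers, sigmas, amps):
        half = int(math.ceil(4 * sig))
        r0, r1 = max(0, int(cr) - half), min(n_rows, int(cr) + half + 1)
        c0, c1 = max(0, int(cc) - half), min(n_cols, int(cc) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None] - cr
        cc_ = np.arange(c0, c1)[None, :] - cc
        fld[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc_**2) / (2.0 * sig**2))
    return fld


def _smooth_field(rng, shape, sigma_cells: float) -> np.ndarray:
    """Standardized smoothed white noise (mean 0, sd 1)."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells)
    sd = z.std()
    return z / sd if sd > 0 else z


def make_country(
    seed: int,
    n_units: int = 100,
    grid_size: tuple[int, int] = (100, 100),
    cell_size: float = 100.0,
    clusters_per_unit: float = 2.5,
    beta: tuple[float | None, float, float] = (None, -4.0, 1.0),
    noise_sd: float = 0.15,
    mean_unit_pop: float = 150.0,
    water_fraction: float = 0.04,
    built_threshold: float = 0.55,
    town_fraction: float = 0.03,
    variants: dict | None = None,
) -> SyntheticCountry:
    """Generate a synthetic country; deterministic in ``seed``.

    ``beta = (b0, b1, b2)`` are the generative coefficients on (intercept,
    DTE in km, lights); ``b0 = None`` calibrates the intercept so the
    expected national total is ``mean_unit_pop * n_units``.  Defaults give
    a settlement-concentrated density (negative DTE coefficient: density
    falls with distance from built edges) with moderate smooth noise —
    conditions under which a unit-level density forest is informative but
    not trivially perfect.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid_size
    grid = GridSpec(0.0, n_rows * cell_size, cell_size, n_rows, n_cols, PLANAR_CRS)
    shape = grid.shape

    # --- settlement truth: Poisson-placed Gaussian clusters, thresholded
    n_clusters = max(3, rng.poisson(clusters_per_unit * n_units))
    centers = rng.uniform([0, 0], [n_rows, n_cols], size=(n_clusters, 2))
    # mostly villages, a few towns/cities: larger, brighter, denser
    is_town = rng.random(n_clusters) < town_fraction
    sigmas = np.where(is_town, rng.uniform(2.5, 4.0, n_clusters),
                      rng.uniform(0.6, 1.4, n_clusters))
    amps = np.where(is_town, rng.uniform(1.5, 3.0, n_clusters),
                    rng.uniform(0.55, 1.1, n_clusters))
    settlement_field = _paint_clusters(shape, centers, sigmas, amps)
    built = settlement_field > built_threshold
    if not built.any() or built.all():
        raise ValidationError("degenerate settlement field; adjust parameters")
    built_vals = built.astype(np.uint8)
    built_truth = BuiltMask(
        Raster(grid, built_vals, nodata=MASK_NODATA), "synthetic", "truth at 100 m"
    )

    # --- land cover: water lake(s), urban = built, two background classes
    water_field = _smooth_field(rng, shape, 12.0)
    water = water_field > np.quantile(water_field, 1.0 - water_fraction)
    water &= ~built  # settlements out-rank water
    climate = _smooth_field(rng, shape, 15.0)
    lc_vals = np.where(climate > 0, LC_CROPLAND, LC_WOODY)
    lc_vals = np.where(water, LC_WATER, lc_vals)
    lc_vals = np.where(built, LC_URBAN, lc_vals)

    # --- tessellation (before the mask so fully-wet units can be repaired)
    finest = make_tessellation(n_units, grid)
    zones = rasterize_units(finest, grid)
    # guarantee every unit keeps >= 1 non-water cell: drain lakes that
    # would otherwise swallow a unit whole
    for zi in range(n_units):
        cells = zones.values == zi
        if np.all(lc_vals[cells] == LC_WATER):
            lc_vals[cells & water] = LC_WOODY
            water[cells] = False
    landcover = Raster(grid, lc_vals.astype(np.int32), nodata=-9999)

    boundary = shapely.box(*grid.bounds)
    mask = build_analysis_mask(landcover, boundary, buffer_km=8.0, water_classes=(LC_WATER,))

    # --- covariates
    dte_true = distance_to_edge(built_truth).raster.values  # metres, signed
    # brightness grows with settlement intensity (cities outshine
    # villages) and decays with distance from the built edge
    lights = (
        1.2 * settlement_field
        + 1.5 * np.exp(-np.maximum(dte_true, 0.0) / 400.0)
        + 0.3 * _smooth_field(rng, shape, 6.0)
        + 0.1 * rng.standard_normal(shape)
    )
    decoy1 = _smooth_field(rng, shape, 5.0)
    decoy2 = _smooth_field(rng, shape, 5.0)

    # --- generative density: log-linear in DTE (km) and lights
    b0, b1, b2 = beta
    eta = b1 * (dte_true / 1000.0) + b2 * lights + noise_sd * _smooth_field(rng, shape, 2.0)
    valid = (mask.values == 1) & mask.valid
    if b0 is None:
        target_total = mean_unit_pop * n_units
        b0 = math.log(target_total / np.exp(eta[valid]).sum())
    lam = np.full(shape, np.nan)
    lam[valid] = np.exp(b0 + eta[valid])
    true_density = Raster(grid, lam)

    # --- census counts: Poisson draws of per-unit expected totals
    lam_fill = np.where(valid, lam, 0.0)
    unit_lambda = np.bincount(
        zones.values[zones.valid], weights=lam_fill[zones.valid], minlength=n_units
    )
    pops = rng.poisson(unit_lambda).astype(np.float64)
    finest = CensusUnitSet(
        finest.unit_ids,
        finest.geometries,
        pops,
        finest.areas_km2,
        level_tag="finest",
        crs_id=PLANAR_CRS,
    )

    # --- degraded settlement variants at their native grids, then aligned
    profiles = VARIANT_PROFILES if variants is None else variants
    aligned: dict[str, BuiltMask] = {}
    for name, prof in profiles.items():
        native = degrade_mask(
            built_truth, seed=int(rng.integers(2**31 - 1)), **prof
        )
        res = resample_presence(native, grid)
        res.source_tag = name
        aligned[name] = res
    if len(aligned) > 1:
        aligned["COMBO"] = combine_masks(list(aligned.values()))

    # --- covariate stack: one DTE layer per settlement variant + fields
    layers: dict[str, Raster] = {}
    for name, vm in aligned.items():
        if name == "COMBO":
            continue
        layers[f"dte_{name.lower()}"] = distance_to_edge(vm).raster
    layers["lights"] = Raster(grid, lights)
    layers["climate"] = Raster(grid, climate)
    layers["decoy1"] = Raster(grid, decoy1)
    layers["decoy2"] = Raster(grid, decoy2)
    stack = assemble_stack(layers, grid, mask)

    params = {
        "seed": seed,
        "n_units": n_units,
        "grid_size": list(grid_size),
        "cell_size": cell_size,
        "beta": [b0, b1, b2],
        "noise_sd": noise_sd,
        "n_clusters": int(n_clusters),
        "mean_unit_pop": mean_unit_pop,
        "water_fraction": water_fraction,
    }
    return SyntheticCountry(
        grid=grid,
        true_density=true_density,
        built_truth=built_truth,
        built_variants=aligned,
        stack=stack,
        finest_units=finest,
        finest_zones=zones,
        boundary=boundary,
        landcover=landcover,
        params=params,
    )


def degrade_mask(
    built_truth: BuiltMask,
    omission_rate: float = 0.0,
    commission_rate: float = 0.0,
    native_cell_factor: int = 1,
    seed: int = 0,
) -> BuiltMask:
    """Emulate a real settlement product's error modes.

    Whole settlement clusters (8-connected components) are omitted with
    probability ``omission_rate``; ``commission_rate`` times the built-cell
    count of scattered single-cell false positives are added; the result is
    regenerated on a native grid ``native_cell_factor`` times finer than
    the truth grid, so downstream presence resampling is exercised.  With
    zero rates and factor 1 the truth is returned unchanged.
    """
    if not (0.0 <= omission_rate < 1.0 and 0.0 <= commission_rate < 1.0):
        raise ValidationError("rates must be in [0, 1)")
    f = int(native_cell_factor)
    if f < 1:
        raise ValidationError("native_cell_factor must be >= 1")
    rng = np.random.default_rng(seed)
    built = built_truth.built.copy()
    valid = built_truth.raster.valid

    if omission_rate > 0:
        labels, n_lab = ndimage.label(built, structure=np.ones((3, 3), int))
        drop = np.flatnonzero(rng.random(n_lab) < omission_rate) + 1
        if drop.size:
            built[np.isin(labels, drop)] = False

    # upsample to the native grid
    if f > 1:
        built_n = np.kron(built, np.ones((f, f), dtype=bool))
        valid_n = np.kron(valid, np.ones((f, f), dtype=bool))
    else:
        built_n, valid_n = built, valid.copy()

    n_comm = int(round(commission_rate * built_n.sum()))
    if n_comm > 0:
        open_cells = np.flatnonzero(valid_n.ravel() & ~built_n.ravel())
        pick = rng.choice(open_cells, size=min(n_comm, open_cells.size), replace=False)
        flat = built_n.ravel()
        flat[pick] = True
        built_n = flat.reshape(built_n.shape)

    g = built_truth.grid
    native_grid = GridSpec(
        g.origin_x, g.origin_y, g.cell_size / f, g.n_rows * f, g.n_cols * f, g.crs_id
    )
    vals = np.where(built_n, 1, 0).astype(np.uint8)
    vals[~valid_n] = MASK_NODATA
    return BuiltMask(
        Raster(native_grid, vals, nodata=MASK_NODATA),
        built_truth.source_tag,
        f"native cell {g.cell_size / f:g}",
    )
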
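"""The three top-down disaggregation models.

Model 1 (binary dasymetric)
    Census counts are spread uniformly over the built cells of each unit:
    weight 1 inside the settlement mask, 0 outside.

Model 2 (random forest + dasymetric)
    A regression forest is trained on the aggregated census level — response
    ``y_i = log(P_i / A_i)`` (log population density, people/km²),
    predictors the zonal means of every covariate layer — then evaluated at
    every pixel on the pixel's own covariate values and back-transformed
    ``exp(yhat)`` into a strictly positive relative density weight.
    Redistribution runs over the whole continuous weight surface.

Model 3 (hybrid)
    The identical forest weight surface, masked to built cells before
    redistribution: non-built cells receive exactly zero population while
    the forest's predictive detail sets the within-settlement gradient.

All three share the pycnophylactic redistribution core

    p_ij = P_i * w'_ij / sum_j w'_ij,     w' = w * constraint,

so per-unit pixel sums reproduce the census counts exactly (to float
tolerance).  Units whose constrained weights sum to zero — census units
with no built pixel — go through a three-pass widening fallback rather
than silently losing population: (1) built cells within the unit; (2)
cells of the unit within a one-cell dilation of the built mask; (3)
uniform over all valid cells of the unit.  The pass used is logged per
unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .builtarea import BuiltMask
from .covariates import CovariateStack, zonal_stat_stack
from .errors import AlignmentError, ValidationError
from .geoio import CensusUnitSet, GridSpec, Raster, ZoneRaster

__all__ = [
    "WeightSurface",
    "ForestModel",
    "PopulationRaster",
    "uniform_weights",
    "redistribute",
    "handle_empty_units",
    "fit_density_forest",
    "predict_weight_surface",
    "run_model",
]

MIN_TRAINING_UNITS = 20


@dataclass
class WeightSurface:
    """Non-negative relative population-density weights per pixel."""

    raster: Raster
    kind_tag: str  # "uniform" | "forest"

    def __post_init__(self) -> None:
        vals = self.raster.values[self.raster.valid]
        if vals.size and np.nanmin(vals) < 0:
            raise ValidationError("weights must be non-negative")


@dataclass
class ForestModel:
    """A fitted density-weighting forest plus its reporting quantities.

    ``oob_variance_explained`` is the out-of-bag R² in percent — the
    forest's goodness-of-fit estimated from samples excluded from each
    tree's bootstrap.  ``importance`` is the per-predictor increase in
    mean-squared error under permutation.
    """

    estimator: RandomForestRegressor
    n_trees: int
    mtry: int
    min_node_size: int
    predictor_names: list[str]
    oob_variance_explained: float
    importance: pd.Series
    seed: int
    degenerate: bool = False  # constant response; fit is uninformative
    pseudo_count_units: list = field(default_factory=list)


@dataclass
class PopulationRaster:
    """People per pixel; per-unit sums equal the census counts."""

    raster: Raster
    model_tag: str  # "model1" | "model2" | "model3"
    built_tag: str  # "WSF" | "GHSL" | "HRSL" | "COMBO" | "none" | ...
    fallback_log: dict = field(default_factory=dict)  # unit_id -> pass (1|2|3)

    def total(self) -> float:
        return float(np.nansum(self.raster.values[self.raster.valid]))


def uniform_weights(grid: GridSpec, valid: np.ndarray) -> WeightSurface:
    """Weight 1 on every valid analysis cell (areal weighting)."""
    vals = np.full(grid.shape, np.nan)
    vals[valid] = 1.0
    return WeightSurface(Raster(grid, vals), "uniform")


def handle_empty_units(
    zone_values: np.ndarray,
    zone_indices: np.ndarray,
    weights: np.ndarray,
    valid: np.ndarray,
    constraint_built: np.ndarray | None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Widening fallback weights for units with zero constrained weight.

    Returns per-cell replacement weights (nonzero only on cells of the
    failing units) and a map of zone index -> fallback pass used.  Pass 1
    is the normal constrained path and never appears here; pass 2 uses the
    unit's cells within a one-cell (3x3) dilation of the built mask; pass 3
    distributes uniformly over all valid cells of the unit.
    """
    extra = np.zeros_like(weights)
    passes: dict[int, int] = {}
    if zone_indices.size == 0:
        return extra, passes
    dilated = None
    if constraint_built is not None:
        dilated = ndimage.binary_dilation(constraint_built, structure=np.ones((3, 3), bool))
    for zi in zone_indices:
        unit_cells = (zone_values == zi) & valid
        if not unit_cells.any():
            raise ValidationError(f"unit index {zi} has zero valid cells")
        if dilated is not None:
            near = unit_cells & dilated
            w_near = np.where(near, weights, 0.0)
            if w_near.sum() > 0:
                extra += w_near
                passes[int(zi)] = 2
                continue
        extra[unit_cells] = 1.0
        passes[int(zi)] = 3
    return extra, passes


def redistribute(
    units: CensusUnitSet,
    zones: ZoneRaster,
    weights: WeightSurface,
    constraint: BuiltMask | None = None,
    model_tag: str = "model2",
    built_tag: str = "none",
) -> PopulationRaster:
    """Mass-preserving dasymetric redistribution of census counts.

    ``p_ij = P_i * w'_ij / sum_j w'_ij`` with ``w' = w * constraint`` when a
    built-mask constraint is given.  Every unit's population is fully
    placed; units needing the fallback are recorded in ``fallback_log``.
    """
    grid = zones.grid
    if not weights.raster.grid.aligned_with(grid):
        raise AlignmentError("weights not aligned to zones")
    if constraint is not None and not constraint.grid.aligned_with(grid):
        raise AlignmentError("constraint not aligned to zones")
    if list(zones.unit_ids) != list(units.unit_ids):
        raise ValidationError("zone raster was built for a different unit set")

    valid = zones.valid & weights.raster.valid
    w = np.where(valid, weights.raster.values, 0.0).astype(np.float64)
    built = constraint.built if constraint is not None else None
    w_eff = w * built if built is not None else w.copy()

    n = len(units)
    zvals = zones.values
    zl = np.where(valid, zvals, -1)
    flat_ok = zl >= 0
    wsum = np.bincount(zl[flat_ok], weights=w_eff[flat_ok], minlength=n)
    cell_counts = np.bincount(zl[flat_ok], minlength=n)
    if np.any(cell_counts == 0):
        missing = [units.unit_ids[i] for i in np.flatnonzero(cell_counts == 0)]
        raise ValidationError(f"units with no valid cells: {missing}")

    fallback_log: dict = {}
    empty = np.flatnonzero((wsum <= 0) & (units.populations > 0))
    if empty.size:
        extra, passes = handle_empty_units(zvals, empty, w, valid, built)
        w_eff += extra
        wsum = np.bincount(zl[flat_ok], weights=w_eff[flat_ok], minlength=n)
        fallback_log = {units.unit_ids[zi]: p for zi, p in passes.items()}

    per_cell_pop = np.zeros(grid.shape, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(wsum > 0, units.populations / np.maximum(wsum, 1e-300), 0.0)
    per_cell_pop[flat_ok] = w_eff[flat_ok] * scale[zl[flat_ok]]
    out = np.full(grid.shape, np.nan)
    out[valid] = per_cell_pop[valid]
    return PopulationRaster(Raster(grid, out), model_tag, built_tag, fallback_log)


def fit_density_forest(
    agg_units: CensusUnitSet,
    stack: CovariateStack,
    zones: ZoneRaster,
    n_trees: int = 500,
    seed: int = 0,
    mtry: int | None = None,
    min_node_size: int = 5,
    importance_repeats: int = 5,
) -> ForestModel:
    """Fit the population-density regression forest on aggregated units.

    Response: log density ``log(P_i / A_i)`` per aggregated unit, with a
    pseudo-count ``log((P_i + 0.5) / A_i)`` for zero-population units so
    they stay in training (logged in ``pseudo_count_units``).  Predictors:
    the zonal mean of every stack layer over the unit.  The forest uses
    ``n_trees`` trees (default 500, enough for stable out-of-bag error),
    ``mtry = max(1, floor(p/3))`` candidate predictors per split and a
    minimum terminal-node size of 5 — standard regression-forest defaults.
    """
    if list(zones.unit_ids) != list(agg_units.unit_ids):
        raise ValidationError("zone raster does not match the aggregated units")
    if len(agg_units) < MIN_TRAINING_UNITS:
        raise ValidationError(
            f"need >= {MIN_TRAINING_UNITS} aggregated units, got {len(agg_units)}"
        )
    if np.any(agg_units.areas_km2 <= 0):
        raise ValidationError("all unit areas must be positive")

    zt = zonal_stat_stack(stack, zones, "mean")
    X = zt.table.to_numpy(dtype=np.float64)
    keep = ~np.isnan(X).any(axis=1)
    if keep.sum() < MIN_TRAINING_UNITS:
        raise ValidationError("too few units with covariate coverage")
    pops = agg_units.populations[keep]
    areas = agg_units.areas_km2[keep]
    pseudo = [
        uid for uid, p, k in zip(agg_units.unit_ids, agg_units.populations, keep)
        if k and p == 0
    ]
    y = np.log(np.where(pops > 0, pops, 0.5) / areas)
    X = X[keep]

    names = list(zt.table.columns)
    p = len(names)
    mtry = mtry if mtry is not None else max(1, p // 3)
    degenerate = bool(np.ptp(y) < 1e-12)

    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node_size,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    oob = 0.0 if degenerate else float(rf.oob_score_) * 100.0

    perm = permutation_importance(
        rf,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=importance_repeats,
        random_state=seed,
    )
    importance = pd.Series(perm.importances_mean, index=names, name="mse_increase")

    return ForestModel(
        estimator=rf,
        n_trees=n_trees,
        mtry=mtry,
        min_node_size=min_node_size,
        predictor_names=names,
        oob_variance_explained=oob,
        importance=importance,
        seed=seed,
        degenerate=degenerate,
        pseudo_count_units=pseudo,
    )


def predict_weight_surface(model: ForestModel, stack: CovariateStack) -> WeightSurface:
    """Per-pixel forest prediction back-transformed to a density weight.

    Each pixel is scored on its own covariate values and the prediction is
    exponentiated, so weights are strictly positive and finite everywhere
    on the valid footprint.  No area normalization is needed: the
    redistribution step renormalizes within each unit.
    """
    missing = [n for n in model.predictor_names if n not in stack.layers]
    if missing:
        raise ValidationError(f"stack lacks predictor layers {missing}")
    X, valid = stack.matrix(model.predictor_names)
    yhat = model.estimator.predict(X)
    w = np.exp(yhat)
    if not np.all(np.isfinite(w)):
        raise ValidationError("non-finite forest weights")
    vals = np.full(stack.grid.shape, np.nan)
    vals[valid] = w
    return WeightSurface(Raster(stack.grid, vals), "forest")


def run_model(
    model_type: int,
    units: CensusUnitSet,
    zones: ZoneRaster,
    stack: CovariateStack | None = None,
    built: BuiltMask | None = None,
    seed: int = 0,
    weights: WeightSurface | None = None,
    n_trees: int = 500,
) -> PopulationRaster:
    """Run one of the three disaggregation models.

    ======  =========================  ==========  =================
    model   weights                    constraint  output raster
    ======  =========================  ==========  =================
    1       uniform (binary)           built mask  built-restricted
    2       forest density surface     none        continuous
    3       forest density surface     built mask  built-restricted
    ======  =========================  ==========  =================

    Models 2 and 3 share the identical weight surface; pass a precomputed
    ``weights`` to reuse one forest across built configurations (and to
    make the sharing explicit).
    """
    if model_type not in (1, 2, 3):
        raise ValidationError("model_type must be 1, 2 or 3")
    if model_type in (1, 3) and built is None:
        raise ValidationError(f"model {model_type} requires a built mask")
    if model_type == 2 and built is not None:
        raise ValidationError("model 2 takes no built mask")

    built_tag = built.source_tag if built is not None else "none"
    if model_type == 1:
        valid = zones.valid
        if stack is not None:
            valid = valid & stack.valid
        w = uniform_weights(zones.grid, valid)
        return redistribute(units, zones, w, built, "model1", built_tag)

    if weights is None:
        if stack is None:
            raise ValidationError("models 2/3 need a covariate stack or weights")
        forest = fit_density_forest(units, stack, zones, n_trees=n_trees, seed=seed)
        weights = predict_weight_surface(forest, stack)
    tag = f"model{model_type}"
    return redistribute(units, zones, weights, built, tag, built_tag)
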
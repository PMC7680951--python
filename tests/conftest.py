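"""Shared fixtures: toy grids, a small synthetic country, model replicates.

Expensive artifacts (the small country, the fitted forest, the replicate
sweep) are session-scoped so unit tests and acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely

import dasypop as dp
from dasypop.geoio import CensusUnitSet, GridSpec, Raster
from dasypop.synthetic import PLANAR_CRS


def planar_grid(rows: int, cols: int, cell: float = 100.0) -> GridSpec:
    return GridSpec(0.0, rows * cell, cell, rows, cols, PLANAR_CRS)


def box_units(bounds_list, pops, ids=None, crs=PLANAR_CRS) -> CensusUnitSet:
    geoms = [shapely.box(*b) for b in bounds_list]
    ids = ids if ids is not None else list(range(len(geoms)))
    return CensusUnitSet(ids, geoms, pops, crs_id=crs)


@pytest.fixture(scope="session")
def small_country():
    """A 60-unit synthetic country on a 60x60 grid (deterministic)."""
    return dp.make_country(seed=11, n_units=60, grid_size=(60, 60))


@pytest.fixture(scope="session")
def small_agg(small_country):
    """Aggregated units of the small country plus their zone raster."""
    res = dp.aggregate_units(small_country.finest_units, seed=5)
    zones = dp.rasterize_units(res.aggregated_units, small_country.grid)
    return res, zones


@pytest.fixture(scope="session")
def small_forest(small_country, small_agg):
    res, zones = small_agg
    forest = dp.fit_density_forest(
        res.aggregated_units, small_country.stack, zones, n_trees=300, seed=7
    )
    weights = dp.predict_weight_surface(forest, small_country.stack)
    return forest, weights


@pytest.fixture(scope="session")
def model_replicates():
    """Twenty seeded replicates of the model-comparison experiment.

    For each replicate: a fresh synthetic country, aggregation, a density
    forest, then Model 1 (true built mask), Model 3 (true built mask) and
    the areal-weighting baseline, all scored against the withheld finest
    units.  Returns a list of dicts of metric dicts.
    """
    out = []
    for seed in range(20):
        c = dp.make_country(seed=100 + seed, n_units=60, grid_size=(60, 60))
        res = dp.aggregate_units(c.finest_units, seed=seed)
        zones = dp.rasterize_units(res.aggregated_units, c.grid)
        forest = dp.fit_density_forest(res.aggregated_units, c.stack, zones, seed=seed)
        weights = dp.predict_weight_surface(forest, c.stack)
        built = c.built_truth
        m1 = dp.run_model(1, res.aggregated_units, zones, stack=c.stack, built=built)
        m3 = dp.run_model(
            3, res.aggregated_units, zones, stack=c.stack, built=built, weights=weights
        )
        areal = dp.redistribute(
            res.aggregated_units, zones, dp.uniform_weights(c.grid, c.stack.valid)
        )
        out.append(
            {
                "model1": dp.score(m1, c.finest_units, c.finest_zones).metrics,
                "model3": dp.score(m3, c.finest_units, c.finest_zones).metrics,
                "areal": dp.score(areal, c.finest_units, c.finest_zones).metrics,
                "oob": forest.oob_variance_explained,
            }
        )
    return out
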
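"""Census-unit aggregation and the Average Spatial Resolution statistic.

Model training uses a two-thirds aggregate of the finest available census
level: one-third of the units, drawn uniformly at random with no spatial
stratification, are each dissolved into the neighbor sharing the longest
border, until the two-thirds target count is reached.  The finest units are
withheld as validation truth.

ASR (Average Spatial Resolution) — the effective linear size of a census
unit — is ``sqrt(total_area / n_units)`` in km.

Implementation notes
--------------------
Shared-border lengths between every adjacent pair are computed once from
the boundary intersections, then maintained additively through the dissolve
sequence: because the units form a partition, the border a merged unit
shares with a third unit is exactly the sum of its members' borders.  This
is equivalent to recomputing neighbor lengths after every dissolve but
avoids repeated geometry work, keeping national-scale tessellations (tens
of thousands of units) tractable.  Output geometries are materialized once
at the end as unions of each surviving group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.strtree import STRtree

from .errors import AggregationStallError, NoNeighborError, ValidationError
from .geoio import CensusUnitSet

__all__ = [
    "AggregationResult",
    "shared_border_lengths",
    "longest_border_neighbor",
    "aggregate_units",
    "compute_asr",
]

# Borders shorter than this fraction of the mean unit perimeter are treated
# as point contacts, not shared borders.
_LENGTH_EPS = 1e-12


@dataclass
class AggregationResult:
    """Outcome of the dissolve procedure.

    ``merge_log`` records each dissolve as (dissolved_unit_id,
    receiver_unit_id), in order; the receiver id is the surviving unit's id
    at the time of the merge.
    """

    aggregated_units: CensusUnitSet
    merge_log: list[tuple[object, object]]
    seed: int
    target_count: int
    membership: dict = field(default_factory=dict)  # output unit_id -> input unit_ids


def shared_border_lengths(units: CensusUnitSet) -> dict[int, dict[int, float]]:
    """Length of the shared border between every adjacent pair of units.

    Returns an adjacency map ``{i: {j: length}}`` over unit indices,
    symmetric, containing only pairs with positive-length shared boundary
    (point contacts are excluded).
    """
    geoms = units.geometries
    boundaries = [g.boundary for g in geoms]
    tree = STRtree(geoms)
    pairs = tree.query(geoms, predicate="intersects")
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(geoms))}
    for a, b in zip(pairs[0], pairs[1]):
        i, j = int(a), int(b)
        if i >= j:
            continue
        length = boundaries[i].intersection(boundaries[j]).length
        if length > _LENGTH_EPS:
            adj[i][j] = length
            adj[j][i] = length
    return adj


def _best_neighbor(
    nbrs: dict[int, float], unit_ids: list, order_key
) -> int:
    """Neighbor index with the longest border; ties to smallest unit_id."""
    best = None
    best_len = -1.0
    for j, length in nbrs.items():
        if length > best_len + _LENGTH_EPS:
            best, best_len = j, length
        elif abs(length - best_len) <= _LENGTH_EPS and best is not None:
            if order_key(unit_ids[j]) < order_key(unit_ids[best]):
                best = j
    return best


def longest_border_neighbor(unit_id, units: CensusUnitSet):
    """Id of the neighbor sharing the longest border with ``unit_id``.

    Ties on border length are broken deterministically by the smallest
    neighbor unit_id under string ordering of the ids.  Raises
    :class:`NoNeighborError` for a unit with no positive-length shared
    border.
    """
    idx = units.index_of(unit_id)
    geom = units.geometries[idx]
    boundary = geom.boundary
    nbrs: dict[int, float] = {}
    for j, other in enumerate(units.geometries):
        if j == idx:
            continue
        if not geom.intersects(other):
            continue
        length = boundary.intersection(other.boundary).length
        if length > _LENGTH_EPS:
            nbrs[j] = length
    if not nbrs:
        raise NoNeighborError(f"unit {unit_id!r} has no neighbor with shared border")
    best = _best_neighbor(nbrs, units.unit_ids, order_key=str)
    return units.unit_ids[best]


def aggregate_units(
    units: CensusUnitSet,
    fraction: float = 1.0 / 3.0,
    seed: int = 0,
) -> AggregationResult:
    """Dissolve a random ``fraction`` of units into longest-border neighbors.

    ``target_count = floor((1 - fraction) * N)`` units remain; units are
    drawn uniformly at random (independent of size or any stratification)
    without replacement and dissolved one at a time, each into its
    longest-shared-border neighbor at that moment.  Dissolving merges
    geometry and sums population; already-absorbed draws are skipped and
    replaced by new draws.  The output count depends only on N and
    ``fraction``, never on the seed.
    """
    n = len(units)
    if n < 3:
        raise ValidationError("need at least 3 units to aggregate")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    target = int(math.floor(n * (1.0 - fraction) + 1e-9))
    if target < 1:
        raise ValidationError("fraction leaves no units")

    adj = shared_border_lengths(units)
    rng = np.random.default_rng(seed)
    draw_order = rng.permutation(n)

    alive = np.ones(n, dtype=bool)
    pops = units.populations.copy()
    areas = units.areas_km2.copy()
    members: list[list[int]] = [[i] for i in range(n)]
    merge_log: list[tuple[object, object]] = []
    remaining = n
    ids = units.unit_ids

    pos = 0
    while remaining > target:
        if pos >= n:
            raise AggregationStallError(
                f"exhausted draws at {remaining} units (target {target}); "
                "tessellation too disconnected"
            )
        i = int(draw_order[pos])
        pos += 1
        if not alive[i]:
            continue  # absorbed earlier; redraw
        nbrs = adj[i]
        if not nbrs:
            continue  # isolated: skip, replaced by the next draw
        j = _best_neighbor(nbrs, ids, order_key=str)
        # dissolve i into j: receiver j survives
        merge_log.append((ids[i], ids[j]))
        pops[j] += pops[i]
        areas[j] += areas[i]
        members[j].extend(members[i])
        # merge adjacency: borders add over partition members
        for k, length in adj[i].items():
            if k == j:
                continue
            adj[j][k] = adj[j].get(k, 0.0) + length
            adj[k][j] = adj[k].get(j, 0.0) + length
            del adj[k][i]
        del adj[j][i]
        adj[i] = {}
        alive[i] = False
        remaining -= 1

    keep = np.flatnonzero(alive)
    out_geoms = []
    for i in keep:
        group = [units.geometries[m] for m in members[i]]
        if len(group) == 1:
            out_geoms.append(group[0])
        else:
            try:
                out_geoms.append(shapely.coverage_union_all(group))
            except shapely.errors.GEOSException:
                out_geoms.append(shapely.union_all(group))
    agg = CensusUnitSet(
        [ids[i] for i in keep],
        out_geoms,
        pops[keep],
        areas[keep],
        level_tag=f"{units.level_tag}+agg" if units.level_tag else "agg",
        crs_id=units.crs_id,
    )
    membership = {ids[i]: [ids[m] for m in members[i]] for i in keep}
    return AggregationResult(
        aggregated_units=agg,
        merge_log=merge_log,
        seed=seed,
        target_count=target,
        membership=membership,
    )


def compute_asr(units: CensusUnitSet) -> float:
    """Average Spatial Resolution in km: sqrt(total area / n_units)."""
    if len(units) == 0:
        raise ValidationError("empty unit set")
    total = units.total_area_km2()
    if total <= 0:
        raise ValidationError("zero total area")
    return math.sqrt(total / len(units))
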
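"""Accuracy assessment against withheld finest-level census units.

Each gridded output is scored by summing people-per-pixel within every
finest-level unit and comparing the sums with the withheld census counts:
root mean squared error (RMSE), percent RMSE (RMSE as a percentage of the
mean observed count), mean absolute error (MAE), and the same RMSE/MAE on
densities (people per km², using UTM-projected unit areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import zonal_stat
from .errors import ValidationError
from .geoio import CensusUnitSet, ZoneRaster
from .models import PopulationRaster

__all__ = ["ValidationReport", "score", "compare_models"]


@dataclass
class ValidationReport:
    """Per-unit observed/predicted counts and the summary error metrics.

    ``pct_rmse`` is normalized by the mean observed count; density metrics
    are in people per km².  Both conventions are recorded in ``meta`` so
    alternates can be derived from the per-unit rows.
    """

    rows: pd.DataFrame  # index unit_id; observed, predicted, area_km2
    metrics: dict[str, float]
    model_tag: str
    built_tag: str
    n_units: int
    excluded_units: list = field(default_factory=list)
    meta: dict = field(
        default_factory=lambda: {
            "pct_rmse_normalizer": "mean_observed",
            "density_units": "people_per_km2",
        }
    )

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "built": self.built_tag,
            "n_units": self.n_units,
            "metrics": self.metrics,
            "excluded_units": list(self.excluded_units),
            "meta": self.meta,
        }


def _error_metrics(obs: np.ndarray, pred: np.ndarray, areas: np.ndarray) -> dict:
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mean_obs = float(np.mean(obs))
    pct_rmse = float(100.0 * rmse / mean_obs) if mean_obs > 0 else float("nan")
    derr = pred / areas - obs / areas
    return {
        "rmse": rmse,
        "pct_rmse": pct_rmse,
        "mae": mae,
        "rmse_density": float(np.sqrt(np.mean(derr**2))),
        "mae_density": float(np.mean(np.abs(derr))),
    }


def score(
    pop: PopulationRaster,
    finest_units: CensusUnitSet,
    zones_finest: ZoneRaster,
) -> ValidationReport:
    """Score a population raster against finest-level census counts.

    ``predicted_i`` is the zonal sum of people-per-pixel over unit i.
    Finest units claiming zero grid cells cannot be scored; they are
    excluded and listed in ``excluded_units``.
    """
    if list(zones_finest.unit_ids) != list(finest_units.unit_ids):
        raise ValidationError("finest zone raster does not match the unit set")
    zt = zonal_stat(pop.raster, zones_finest, "sum")
    pred = zt.table["value"].to_numpy()
    obs = finest_units.populations
    areas = finest_units.areas_km2
    ok = ~np.isnan(pred)
    excluded = [u for u, k in zip(finest_units.unit_ids, ok) if not k]
    rows = pd.DataFrame(
        {
            "observed": obs[ok],
            "predicted": pred[ok],
            "area_km2": areas[ok],
        },
        index=pd.Index([u for u, k in zip(finest_units.unit_ids, ok) if k], name="unit_id"),
    )
    metrics = _error_metrics(obs[ok], pred[ok], areas[ok])
    return ValidationReport(
        rows=rows,
        metrics=metrics,
        model_tag=pop.model_tag,
        built_tag=pop.built_tag,
        n_units=int(ok.sum()),
        excluded_units=excluded,
    )


def compare_models(reports: list[ValidationReport]) -> pd.DataFrame:
    """Rank model/built configurations by RMSE, flagging per-metric minima.

    All reports must have been scored against the same finest units.
    Returns a table sorted by RMSE with ``is_min_<metric>`` boolean columns
    marking the best configuration per metric.
    """
    if not reports:
        raise ValidationError("no reports to compare")
    n0 = reports[0].n_units
    if any(r.n_units != n0 for r in reports):
        raise ValidationError("reports score different unit sets")
    recs = []
    for r in reports:
        rec = {"model": r.model_tag, "built": r.built_tag}
        rec.update(r.metrics)
        recs.append(rec)
    df = pd.DataFrame(recs)
    metric_cols = [c for c in df.columns if c not in ("model", "built")]
    for c in metric_cols:
        df[f"is_min_{c}"] = df[c] == df[c].min()
    return df.sort_values("rmse").reset_index(drop=True)
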
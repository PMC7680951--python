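"""Harmonize settlement masks: binarize, presence-resample, union, DTE.

Settlement products arrive at different native resolutions.  Each is
resampled to the analysis grid by presence/non-presence (a coarse cell is
built iff any overlapping native cell is built), combined into a union
layer, and turned into signed distance-to-outer-edge covariates.
"""

import numpy as np

import dasypop as dp

country = dp.make_country(seed=3, n_units=60, grid_size=(60, 60))
truth = country.built_truth

# a variant observed on a 3x-finer native grid, with omissions/commissions
native = dp.degrade_mask(truth, omission_rate=0.2, commission_rate=0.05,
                         native_cell_factor=3, seed=1)
print(f"native grid: {native.grid.n_rows}x{native.grid.n_cols} cells of "
      f"{native.grid.cell_size:.0f} m")

aligned = dp.resample_presence(native, country.grid)
print(f"aligned to analysis grid: {aligned.built_count()} built cells "
      f"(truth has {truth.built_count()})")

combo = dp.combine_masks([aligned, truth])
print(f"union mask: {combo.built_count()} built cells "
      f">= max of members ({max(aligned.built_count(), truth.built_count())})")

dte = dp.distance_to_edge(aligned)
v = dte.raster.values
print(f"DTE range: {np.nanmin(v):.0f} m (deepest interior) to "
      f"{np.nanmax(v):.0f} m (farthest from settlement)")
# Negative inside built features, positive outside; the magnitude is the
# Euclidean distance in metres to the nearest opposite-class cell.
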
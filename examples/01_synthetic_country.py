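"""Generate a synthetic country and inspect its ingredients.

Builds a 100-unit country on a 100x100 grid of 100 m cells: a settlement
truth mask, three degraded settlement variants plus their union, a
covariate stack, and census counts drawn from a known log-linear density.
"""

import numpy as np

import dasypop as dp

country = dp.make_country(seed=7, n_units=100, grid_size=(100, 100))

units = country.finest_units
print(f"finest units: {len(units)}, total population {units.total_population():.0f}")
print(f"ASR (effective unit size): {dp.compute_asr(units):.2f} km")
print(f"settlement truth: {country.built_truth.built_count()} built cells "
      f"({100 * country.built_truth.built.mean():.1f}% of the grid)")
for name, mask in country.built_variants.items():
    print(f"  variant {name:5s}: {mask.built_count():5d} built cells")
print("covariate layers:", ", ".join(country.stack.names))

lam = country.true_density.values
built = country.built_truth.built & country.stack.valid
share = np.nansum(lam[built]) / np.nansum(lam[country.stack.valid])
print(f"{100 * share:.0f}% of expected population mass lies inside built cells")
# The variants differ from the truth through omissions (dropped
# settlements), commissions (false positives) and native-resolution
# resampling, which is what the model comparison is about.
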
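"""Compare normal and growth-restricted arterial cohorts.

Generates two seeded 6-cast cohorts (calibrated to the published group
medians), computes each cast's ground-truth length density through the
morphometry route, and runs the exact Mann-Whitney test — the study's
headline comparison.
"""

import numpy as np

from vasculocast import generate_cohort, get_preset
from vasculocast.groupstats import mann_whitney, median_iqr
from vasculocast.morphometry import filter_by_diameter, length_density, segment_table_from_tree

densities = {}
for name in ("normal_arterial", "fgr_arterial"):
    preset = get_preset(name)
    casts = generate_cohort(name, n_casts=6, seed=7, render=False)
    densities[name] = [
        length_density(
            filter_by_diameter(segment_table_from_tree(tree), 100.0),
            preset.tissue_volume_cm3,
        )
        for _, tree in casts
    ]

for name, vals in densities.items():
    med, (q25, q75) = median_iqr(np.array(vals))
    print(f"{name}: median {med:.2f} mm/cm^3 (IQR {q25:.2f}-{q75:.2f})")

u, p = mann_whitney(densities["normal_arterial"], densities["fgr_arterial"])
print(f"Mann-Whitney U = {u:.0f}, exact two-sided p = {p:.4f}")
print("FGR arterial density is lower" if
      np.median(densities["fgr_arterial"]) < np.median(densities["normal_arterial"])
      else "no deficit in this draw")
# The deficit of arterial length density in growth restriction is the
# study's central finding; with 6 casts per group the exact permutation
# null (C(12,6) = 924 assignments) decides significance.
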
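"""Group comparison and rater agreement on phantom-scale data.

Builds two small groups of phantoms that differ in HRF load, compares their
HRF volumes with the two-sided Mann-Whitney U test, and shows weighted
kappa for an ordinal two-rater grading table.
"""

import mcoct
from mcoct.stats import group_summary, mann_whitney_u, weighted_kappa

with_hrf = [
    mcoct.run_pipeline(mcoct.RunConfig(preset="ped_with_hrf", seed=s)).report.hrf_volume_mm3
    for s in range(5)
]
without = [
    mcoct.run_pipeline(mcoct.RunConfig(preset="ped_with_defect", seed=s)).report.hrf_volume_mm3
    for s in range(5, 10)
]
u, p = mann_whitney_u(with_hrf, without)
print("HRF volumes (mm^3), phantoms with HRF :", [f"{v:.5f}" for v in with_hrf])
print("HRF volumes (mm^3), phantoms without  :", [f"{v:.5f}" for v in without])
print(f"Mann-Whitney U = {u:.0f}, two-sided p = {p:.4f}")
print(group_summary(with_hrf, "with HRF", "mm^3"))

# two raters grading 24 items on a 3-category ordinal scale
rater_a = [1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3, 3, 2]
rater_b = [1, 1, 1, 2, 1, 2, 2, 2, 2, 2, 2, 3, 2, 2, 3, 3, 3, 3, 3, 3, 2, 3, 3, 2]
for scheme in ("linear", "quadratic"):
    k = weighted_kappa(rater_a, rater_b, weights=scheme)
    print(f"weighted kappa ({scheme:9s}) = {k:.2f}")
print("\nfully separated groups of five reject at alpha = 0.05; a weighted "
      "kappa in the high 0.8s indicates substantial ordinal agreement.")
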
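"""Detect a focal RPE-melanin defect and measure its area with F_RPE.

Runs the full pipeline on a phantom with a known rectangular defect and
compares the recovered area (sum of per-B-scan defect lengths x B-scan
pitch) with the ground truth footprint.
"""

import mcoct

result = mcoct.run_pipeline(mcoct.RunConfig(preset="ped_with_defect", seed=1))
_vol, truth = mcoct.build_phantom(mcoct.default_spec("ped_with_defect", seed=1))
spec = mcoct.default_spec("ped_with_defect", seed=1)

true_area = truth.defect_footprint.sum() * spec.dx * spec.dy
print(f"F_RPE threshold      : {result.report.thresholds['frpe']}")
print(f"OCTA Otsu threshold  : {result.report.thresholds['octa_otsu']:.4f}")
print(f"defects detected     : {len(result.report.defects)}")
for d in result.report.defects:
    scans = sorted(d.runs)
    print(f"  defect {d.defect_id}: {d.area_mm2:.4f} mm^2 across "
          f"B-scans {scans[0]}-{scans[-1]}")
print(f"total area           : {result.report.total_defect_area_mm2:.4f} mm^2")
print(f"ground-truth area    : {true_area:.4f} mm^2")
print("\nthe recovered area tracks the simulated melanin defect; the ~1-column"
      "\nboundary blur reflects the 3-pixel transverse contrast kernels.")
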
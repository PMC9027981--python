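"""Per-pixel pH mapping of one simulated scan.

Runs the full per-pixel chain (smoothing, spectral interpolation, B0
correction, MTR asymmetry at both powers, QC, RPM, linear calibration) on a
phantom whose compartments sit at different pH, then summarizes the pH map
per tissue ROI.
"""

import numpy as np

from acidocest import build_phantom, roi_mean_ph, simulate_acquisition
from acidocest.experiments import calibrate_from_phantoms, process_acquisition

TRUE_PH = {1: 6.5, 2: 6.9, 3: 7.3}
NAMES = {1: "cartilage", 2: "meniscus", 3: "fluid"}

# tissue-matched calibration from uniform-pH phantom scans
cal_scans = []
for i, level in enumerate((6.2, 6.6, 7.0, 7.4, 7.8)):
    ph = build_phantom(matrix_size=(48, 48, 6),
                       ph_by_tissue={1: level, 2: level, 3: level}, seed=10 + i)
    cal_scans.append(simulate_acquisition(ph, noise_sigma=0.02, seed=10 + i))
lines = calibrate_from_phantoms(cal_scans, agent="iohexol")
for lab, line in lines.items():
    print(f"{NAMES[lab]:>9} calibration: RPM = {line.slope:.3f} * pH - {line.intercept:.3f}")

phantom = build_phantom(matrix_size=(48, 48, 6), ph_by_tissue=TRUE_PH, seed=42)
acq = simulate_acquisition(phantom, noise_sigma=0.02, seed=42)
res = process_acquisition(acq, line=lines)

print(f"\nslices processed: {res.n_slices}")
print("QC rejection counts (0 = pass):", res.rejection_counts)
for lab, name in NAMES.items():
    mean, n = roi_mean_ph(res.ph_map, res.qc, phantom.labels, lab)
    print(f"{name:>9}: true pH {TRUE_PH[lab]:.1f}, "
          f"recovered {mean:.3f} over {n} QC-passing voxels")
print("\nRecovered ROI means track the ground truth to a few hundredths of a"
      "\npH unit; QC-rejected voxels (coded reasons) are excluded, not zeroed.")
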
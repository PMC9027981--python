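"""Simulate a CEST scan of the digital knee phantom and look at a Z-spectrum.

Builds the three-compartment phantom (cartilage / meniscus / fluid), runs the
Bloch-McConnell acquisition simulation at the two saturation powers, and
prints one cartilage voxel's Z-spectrum together with its MTR asymmetry at
the analysis offset.
"""

import numpy as np

from acidocest import build_phantom, simulate_acquisition, ppm_to_hz

phantom = build_phantom(matrix_size=(32, 32, 4),
                        ph_by_tissue={1: 6.8, 2: 7.0, 3: 7.2},
                        b0_amplitude_hz=30.0, seed=1)
print("compartment sizes:",
      {lab: int((phantom.labels == lab).sum()) for lab in (1, 2, 3)})

acq = simulate_acquisition(phantom, agent="iohexol", noise_sigma=0.0, seed=1)
wf = acq.acquisition.water_frequency_mhz
f_a = ppm_to_hz(4.3, wf)
print(f"water frequency {wf:.3f} MHz; analysis offset +4.3 ppm = {f_a:.1f} Hz")

vox = tuple(np.argwhere(phantom.labels == 1)[40])
print(f"\ncartilage voxel {vox} (pH 6.8), normalized signal per offset:")
print(f"{'offset Hz':>10} {'0.54 uT':>9} {'1.10 uT':>9}")
ref = acq.reference[vox]
by_power = {}
for (f, b1), idx in zip(acq.channels, range(len(acq.channels))):
    by_power.setdefault(b1, {})[f] = acq.signals[vox][idx] / ref
for f in sorted(by_power[0.54]):
    print(f"{f:>10.0f} {by_power[0.54][f]:>9.4f} {by_power[1.10][f]:>9.4f}")

for b1 in (0.54, 1.10):
    # nearest sampled offsets to +/-549 Hz are +/-550 -> use 550 directly
    m = (by_power[b1][-550.0] - by_power[b1][550.0])
    print(f"MTRasym at ~4.3 ppm, B1 = {b1} uT: {m:.4f}")
print("\nThe dip on the positive (agent) side deepens with saturation power;"
      "\nthat power dependence is what the ratiometric pH readout exploits.")
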
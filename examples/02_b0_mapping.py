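"""Estimate the off-resonance field from the dual-echo pair.

Simulates a phantom with a smooth B0 inhomogeneity, reconstructs the field
map from the phase difference between the two echoes (TE 0.032 / 2.2 ms),
and compares it with the simulation's ground truth.
"""

import numpy as np

from acidocest import DualEchoPair, build_phantom, compute_delta_b0, simulate_acquisition

phantom = build_phantom(matrix_size=(32, 32, 4), b0_amplitude_hz=60.0, seed=3)
acq = simulate_acquisition(phantom, noise_sigma=0.005, seed=3)

pair = DualEchoPair(acq.echo1, acq.echo2,
                    acq.acquisition.te1_ms, acq.acquisition.te2_ms)
b0map = compute_delta_b0(pair, magnitude_floor=0.05)

tissue = phantom.labels > 0
err = b0map.delta_f_hz[tissue] - phantom.b0_field_hz[tissue]
print(f"alias-free range: +/-{1 / (2 * pair.delta_te_s):.1f} Hz")
print(f"tissue voxels: {tissue.sum()}, valid in map: {b0map.valid[tissue].sum()}")
print(f"true field range: [{phantom.b0_field_hz[tissue].min():.1f}, "
      f"{phantom.b0_field_hz[tissue].max():.1f}] Hz")
print(f"recovery error: mean {err.mean():+.3f} Hz, RMS {np.sqrt((err**2).mean()):.3f} Hz")
print("\nBackground voxels fall below the magnitude floor and are masked out;"
      "\nthe recovered field drives the per-pixel spectral re-centering.")
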
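"""Self-calibrated pH recovery on held-out phantoms.

The validation experiment behind the pipeline: fit tissue-matched RPM-pH
lines on one series of uniform-pH phantom scans, apply them to an
independent series, and measure the pooled recovery error.
"""

from acidocest import run_parameter_recovery

res = run_parameter_recovery(seed=5, noise_sigma=0.02, matrix_size=(64, 64, 8))

NAMES = {1: "cartilage", 2: "meniscus", 3: "fluid"}
for lab, line in res.lines.items():
    print(f"{NAMES[lab]:>9}: RPM = {line.slope:.3f} * pH - {line.intercept:.3f} "
          f"over pH {line.valid_ph_range}")

print(f"\n{'tissue':>9} {'true':>5} {'recovered':>9}")
for true, rec, lab in zip(res.true_ph, res.recovered_ph, res.labels):
    print(f"{NAMES[lab]:>9} {true:>5.1f} {rec:>9.3f}")
print(f"\npooled RMSE: {res.rmse:.4f} pH units "
      f"(noise scale {res.details['noise_sigma']}, "
      f"matrix {res.details['matrix_size']})")
print("\nAn RMSE of a few hundredths of a pH unit means the ratiometric"
      "\nreadout plus linear calibration is quantitatively self-consistent.")
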
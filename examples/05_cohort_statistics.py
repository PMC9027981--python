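"""End-to-end cohort study on synthetic data.

Runs the staged pipeline (simulate -> b0map -> calibrate -> process ->
roi-stats) on a small two-group cohort and prints the group contrasts and
the pH-versus-clinical-score correlations from the generated report.
"""

import json
import tempfile
from pathlib import Path

from acidocest import RunConfig, run_pipeline

config = RunConfig(seed=1, n_no_oa=6, n_oa=5, matrix_size=(20, 20, 8),
                   noise_sigma=0.02)
with tempfile.TemporaryDirectory() as td:
    report_dir = run_pipeline(config, td)

    summary = json.loads((report_dir / "summary.json").read_text())
    print(f"subjects: {summary['n_subjects']}, "
          f"slices processed: {summary['total_slices']}")

    contrasts = json.loads((report_dir / "contrasts.json").read_text())
    print("\ngroup contrasts (exact rank-sum unless noted):")
    for c in contrasts["contrasts"]:
        print(f"  {c['contrast']:<35} p = {c['p_value']:.4g}  ({c['method']})")

    correlations = json.loads((report_dir / "correlations.json").read_text())
    print("\nSpearman correlations of mean pH with clinical scores:")
    for row in correlations["correlations"]:
        print(f"  {row['score']:<16} rho = {row['rho']:+.3f}  p = {row['p_value']:.4g}")

print("\nLower pH in the OA arm separates the groups; KOOS subscales rise"
      "\nwith pH (better function) and the pain scale falls (less pain).")
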
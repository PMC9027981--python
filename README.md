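# acidocest

Ratiometric CEST-MRI pH mapping for musculoskeletal imaging: from
multi-offset, dual-power saturation-transfer volumes and a dual-echo B0 map
to per-pixel extracellular pH, ROI summaries and cohort statistics — plus a
Bloch–McConnell synthetic-data generator that provides ground-truth
phantoms and cohorts for end-to-end validation.

The package is written for quantitative-MRI researchers who want to analyze
(or prototype analyses of) acidoCEST acquisitions of joints, where an
acidic extracellular microenvironment accompanies cartilage degeneration
and pain. The intracavitary iodinated agents iopamidol and iohexol carry
amide protons whose exchange with water is base-catalyzed; saturating them
at +4.2 / +4.3 ppm and measuring the water-signal asymmetry at two
saturation powers yields a concentration-independent, pH-sensitive readout.

## The method in brief

Per pixel, with `I0` the unsaturated reference and `Δω` the agent's amide
offset:

    MTRasym = ( I(−Δω) − I(+Δω) ) / I0                       (per power)

    RPM = [ (1−MTRasym)/MTRasym ]_RF1                         (RF1 = 0.54 µT)
          ───────────────────────────
          [ (1−MTRasym)/MTRasym ]_RF2                         (RF2 = 1.10 µT)

    pH  = ( RPM + b ) / a                                     (linear calibration)

Built-in calibrations: iopamidol `pH = (RPM + 10.21)/1.88`, iohexol
`pH = (RPM + 8.39)/1.56`, valid over pH 6.2–7.8. Pixels qualify only when
MTRasym is positive and increases with power; everything else is rejected
with a coded reason. Spectra are Gaussian-smoothed in-plane, interpolated
with cubic splines per spectral side, and re-centered per pixel using the
phase-difference ΔB0 map of a dual-echo pair (TE 0.032 / 2.2 ms). See
`docs/methods.md` for the full model and every default.

## Worked example

Tissue-matched self-calibration and pH recovery on held-out digital
phantoms (`examples/04_calibration_recovery.py`):

```
$ python examples/04_calibration_recovery.py
cartilage: RPM = 0.488 * pH - 1.745 over pH (6.2, 7.8)
 meniscus: RPM = 0.505 * pH - 1.822 over pH (6.2, 7.8)
    fluid: RPM = 0.484 * pH - 1.697 over pH (6.2, 7.8)

   tissue  true recovered
cartilage   6.2     6.201
 meniscus   6.2     6.239
    fluid   6.2     6.217
...
cartilage   7.8     7.820
 meniscus   7.8     7.916
    fluid   7.8     7.771

pooled RMSE: 0.0380 pH units (noise scale 0.02, matrix (64, 64, 8))
```

Five uniform-pH phantoms (pH 6.2–7.8) are scanned, reduced to QC-passing
mean RPM per compartment, and fitted to one line per tissue; an independent
phantom series is then processed into pH maps with those lines. A pooled
RMSE of ~0.04 pH units at SNR 50 (and ~0.001 noise-free) means the
ratiometric readout plus linear calibration recovers ground truth almost to
the noise floor.

The other examples each exercise one capability: `01` simulates a scan and
prints a Z-spectrum, `02` reconstructs the B0 field from the dual-echo
pair, `03` maps pH on a phantom with per-compartment pH, and `05` runs the
whole staged cohort study (16 synthetic knees, 448 slices) and prints the
group contrasts (exact rank-sum / signed-rank) and the Spearman
correlations of mean pH with the six KOOS subscales and the visual-analog
pain score.

A thin CLI mirrors the library:
`acidocest run|simulate|b0map|calibrate|process|roi-stats --help`.

## Layout

```
src/acidocest/
  bloch.py        Bloch–McConnell simulation (CW saturation, steady state)
  synthetic.py    phantoms, acquisitions, cohorts with ground truth
  b0.py           dual-echo phase-difference field mapping
  cest.py         smoothing, interpolation, B0 correction, MTRasym, RPM,
                  QC, calibration — the per-pixel chain
  stats.py        ROI means, exact rank tests, Spearman, cohort report
  experiments.py  tissue-matched calibration + held-out recovery
  io.py           NIfTI + JSON-sidecar, CSV, calibration and config I/O
  pipeline.py     staged, hash-cached simulate→…→report runner
  cli.py          click front end
```
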
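# Methods

`acidocest` implements ratiometric CEST-MRI pH mapping with iodinated
contrast agents: from multi-offset, dual-power saturation-transfer image
stacks and a dual-echo field map to per-pixel pH, ROI summaries and cohort
rank statistics, together with a Bloch–McConnell simulator that supplies
ground-truth phantoms and cohorts for validation.

## The measurement model

Iodinated agents such as iopamidol and iohexol carry amide protons that
exchange with bulk water at a base-catalyzed, pH-dependent rate. Saturating
them at their chemical shift (+4.2/+5.6 ppm for iopamidol, +4.3 ppm for
iohexol) transfers saturation to water; the water-signal loss is read out as
the asymmetry of the Z-spectrum about the water line,

    MTRasym(Δω) = ( I(−Δω) − I(+Δω) ) / I0 ,

where `I0` is a dedicated unsaturated acquisition. Acquiring the same
spectrum at two saturation amplitudes (RF1 = 0.54 µT, RF2 = 1.10 µT,
power-average equivalents of the 32 ms / 40 Hz Fermi pulse) gives the
ratiometric power mismatch

    RPM = [ (1−MTRasym)/MTRasym ]_RF1 / [ (1−MTRasym)/MTRasym ]_RF2 ,

which cancels the agent concentration to first order and increases
monotonically with exchange rate, hence with pH. A linear phantom
calibration `RPM = a·pH − b` is inverted per pixel, `pH = (RPM + b)/a`.
Built-in lines are provided for both agents (iopamidol a = 1.88,
b = 10.21; iohexol a = 1.56, b = 8.39; valid over pH 6.2–7.8); fitted,
tissue-matched lines are preferred wherever calibration scans exist (see
below).

A pixel enters the analysis only if its CEST effect is adequate:
`MTRasym > 0` at both powers and larger at the higher power. Everything else
is rejected with a coded reason (1 non-positive, 2 non-increasing with
power, 3 invalid field map/reference/out-of-range shift). For every passing
pixel `RPM > 1` by construction. Note the rule's operating characteristic:
a pure-noise pixel still passes with roughly 25 % probability (two chance
sign conditions), so QC thins noise rather than eliminating it; the noisy
survivors carry RPM just above 1 and map to low pH unless excluded by ROI
placement.

## Processing chain

Per volume, in order:

1. **Spatial smoothing** — each offset image (and the reference) is smoothed
   with an isotropic in-plane Gaussian, default sigma = 1 voxel. Smoothing
   is 2-D because through-slice resolution is far coarser. Sigma = 0 is the
   identity.
2. **Spectral interpolation and B0 correction** — per pixel, each spectral
   side (7 samples, ±430…±670 Hz in 40 Hz steps; no samples span the water
   line) is interpolated with a natural cubic spline and read out at the
   analysis offset displaced by the pixel's off-resonance:
   `S_corr(f) = S_meas(f + Δf)`. Queries may extrapolate at most one offset
   step (40 Hz) beyond the sampled range; shifts beyond ±120 Hz (three
   steps) mark the pixel invalid rather than extrapolating further.
3. **Asymmetry, QC, RPM, pH** as above. Out-of-range pH values are flagged
   (`clipped_mask`), not censored: low pH is information, not an error.

The ΔB0 map comes from the dual-echo pair (TE1 = 0.032 ms, TE2 = 2.2 ms):
`Δf = arg(S1* · S2) / (2π ΔTE)`. Phase common to both echoes cancels; the
alias-free range at ΔTE = 2.168 ms is ±230.6 Hz, comfortably above the
±120 Hz correction limit, so no unwrapping is attempted. Voxels whose
first-echo magnitude falls below 5 % of the maximum are masked invalid and
set to 0 Hz (explicit mask propagation instead of NaN).

## Calibration

`fit_calibration` is an ordinary least-squares line through (pH, RPM)
points; it requires at least three distinct pH levels and a positive slope.
Because the direct-saturation spillover in RPM depends on the water pool's
relaxation, RPM at fixed pH differs between cartilage, meniscus and fluid
by several tenths. Calibration is therefore *tissue-matched*: one line per
compartment, fitted from uniform-pH phantom scans, with each phantom reduced
to its QC-passing **mean** RPM per compartment — the same reduction the ROI
pH summary applies, so the noise-induced convexity bias of the ratio (the
mean of `1/MTRasym` exceeds `1/mean`) enters calibration and readout alike
and cancels. `process_volume` accepts either a single agent line (the
published-equation workflow) or a per-label mapping plus a label volume.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions every
validation result refers to.

**Acquisition.** Offsets ±430…±670 Hz in 40 Hz steps at 0.54 and 1.10 µT
plus one unsaturated reference (29 channels); 3 T (water frequency
42.577 MHz/T × 3 = 127.731 MHz); dual-echo pair as above. Sequence timing
(TR 62 ms, 5 spokes, 5° flip) is carried as metadata only. Saturation is
modeled as continuous-wave at the power-average amplitude — the standard
desk-scale surrogate for a Fermi pulse train — and spectra are steady-state
solutions of the Bloch–McConnell equations. The public single-spectrum
routine propagates the exact matrix exponential of the affine system; the
volume simulator uses the vectorized closed-form fixed point of the same
linear system (the two agree to 1e-6, enforced by tests).

**Phantom.** A 64×64×8 grid (configurable; 236×236×28 matches the clinical
matrix but is needlessly slow on a desk) with a central elliptical fluid
pool, a cartilage annulus and two meniscus blocks; per-compartment water
relaxation, agent concentration, proton density and ground-truth pH; a
smooth low-order-polynomial B0 field (default ±40 Hz peak) whose
coefficients are the only seeded randomness in the geometry. Rician noise
(magnitude MRI) is applied with scale `noise_sigma` on the proton-density
scale where fluid = 1, so `noise_sigma = 0.02` is SNR 50 on the brightest
compartment.

**Exchange model.** Each amide resonance of an agent is modeled as two
exchange sites obeying the base-catalyzed law `k = k0 + kb·10^(pH−7)`:

| site | k0 (1/s) | kb (1/s) | proton fraction (unit conc.) |
|------|---------:|---------:|------------------------------:|
| fast | 49.67    | 67.70    | 0.0072 |
| slow | 5.228    | 453.3    | 0.0040 |

with amide T1 = 1.09 s, T2 = 1.34 ms. The two-site structure is the
model's central design choice. With a single site the exchange rate is
exponential in pH while RPM is a bounded, sigmoidal function of the rate, so
RPM(pH) is visibly convex and a linear calibration leaves systematic
residuals of ~0.1 pH — contradicting the empirical behavior of these
agents, whose published calibrations are linear over 6.2–7.8. The
superposition of a fast, weakly catalyzed site and a slow, strongly
catalyzed site straightens the curve: with the defaults above the residual
nonlinearity is ~0.001 pH for all three compartments, while MTRasym stays
in the 0.08–0.25 range with the asymmetry strictly increasing in power
(the QC rule) across the whole calibrated span. These constants, and the
tissue table below, were fixed once by fitting the analytic RPM(pH) curves
to those design targets; they are conditions of the simulation study, not
tuning knobs.

**Tissues** (effective values seen by the ultrashort-TE readout; fluid is
contrast-rich synovial fluid, which shortens its native relaxation):

| label | tissue    | water T1 (s) | water T2 (s) | rel. agent conc. | proton density |
|-------|-----------|-------------:|-------------:|-----------------:|---------------:|
| 1     | cartilage | 1.44         | 0.030        | 1.00             | 0.8 |
| 2     | meniscus  | 1.01         | 0.018        | 0.76             | 0.6 |
| 3     | fluid     | 1.85         | 0.045        | 1.00             | 1.0 |

**Cohort.** Two arms (default 9 no-OA, 7 severe-OA); per-subject mean pH
drawn from Normal(7.01, 0.26) and Normal(6.40, 0.08) respectively, clipped
to [6.0, 8.0]; per-tissue pH jittered around the subject mean (sd 0.05).
The first three subjects receive iopamidol, the rest iohexol (the 3:13
agent split of the emulated protocol). KOOS subscales are linear in subject
pH (slope +30 points per pH unit, Gaussian noise sd 6, clipped to [0, 100]);
the visual-analog pain scale has slope −3.3 (sd 0.8, clipped to [0, 10]).
The slopes are chosen so the noise-free links stay strictly inside the score
ranges — at zero link noise every KOOS correlation is exactly +1 and the
pain correlation −1, which the tests assert.

## Statistics

Between-group contrasts use the exact two-sided rank-sum (Mann–Whitney)
test (exact null for tie-free arms up to n = 12, tie-corrected normal
approximation beyond); within-subject tissue contrasts use the exact
Wilcoxon signed-rank test (zero differences dropped; exact null up to
n = 25 tie-free, full sign-pattern enumeration when tied magnitudes occur
at n ≤ 15, normal approximation beyond). Spearman correlation uses
mid-ranks with an exact permutation p for n ≤ 9 and the t approximation
otherwise. Shapiro–Wilk is computed as an annotation only — rank tests are
used regardless. No multiple-testing correction is applied; raw two-sided
p-values are reported. Group summaries weight subjects equally; each
subject's overall mean pH weights QC-passing voxels equally across the
three tissues.

All exact tests are verified against brute-force enumeration oracles
(complete assignment/sign-pattern enumeration) for all arm sizes up to 7.

## Numerical choices and degenerate inputs

* Steady state via `solve(A, −b)` on batched per-voxel systems (6×6 for
  iohexol, 15×15 for iopamidol's two resonances × two sites + water);
  propagation via `expm` of the augmented matrix over 50× the longest T1
  (transients < 1e-17).
* Natural spline boundary conditions; each spectral side interpolated
  independently; one-step extrapolation margin.
* Identical score multisets ⇒ rank-sum p = 1; all-zero paired differences
  ⇒ signed-rank p = 1; single-pair contrasts report p = 1 with a low-n
  warning; constant input ⇒ Spearman rho undefined (NaN, warned).
* ROI means over zero QC-passing voxels are *missing* (None), never 0.
* The staged pipeline hashes stage inputs and outputs; unchanged stages are
  skipped and reruns are byte-identical (NIfTI gzip headers are written
  deterministically). All randomness derives from the single run seed.

## Problem sizes

Default validation sizes keep everything desk-scale: phantom experiments at
64×64×8 (five calibration + five held-out scans per condition), cohort runs
at 24×24×28 (16 subjects × 28 sagittal slices = 448 slices, matching the
emulated study's accounting). At these sizes the full pipeline completes in
well under a minute and the complete phantom-recovery experiment in a few
seconds per condition.

## What the synthetic validation does and does not show

The generator reproduces the features the analysis logic depends on:
spectral sampling and pairing, power-dependent saturation, B0 displacement
and its phase encoding, concentration differences between compartments,
Rician noise, group structure and monotone clinical-score links. It does
**not** contain motion, semisolid magnetization-transfer or nuclear
Overhauser background, partial-volume anatomy beyond smoothing, B1
transmit inhomogeneity, chemical-shift displacement of the readout, or
scanner drift. Passing the recovery and contrast tests therefore shows the
pipeline is correct and self-consistent under its stated model — it does
not certify accuracy on patient data, where calibration transfer across
tissues and background contamination are the dominant open risks. The
fluid compartment's pH is additionally confounded in vivo by the injected
contrast's own pH (6.5–7.7 per the manufacturer), which the simulator can
represent only as a user-chosen fluid pH.
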
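"""Per-pixel CEST processing: smoothing, spectral interpolation, B0
correction, MTR asymmetry, the ratiometric power mismatch, QC filtering and
pH calibration.

The chain implements the standard ratiometric acidoCEST readout:

* ``MTRasym = (I(-dw) - I(+dw)) / I0`` — asymmetry of the Z-spectrum about
  the water line at the analysis offset ``dw``, per saturation power.
* ``RPM = [(1-MTRasym)/MTRasym]_RF1 / [(1-MTRasym)/MTRasym]_RF2`` — ratio of
  the inverse-asymmetry terms at the low (RF1) and high (RF2) power.  For a
  voxel with a genuine CEST effect the asymmetry grows with power, so
  RPM > 1, and RPM increases monotonically with the exchange rate (hence pH)
  while being independent of agent concentration.
* ``pH = (RPM + b) / a`` — agent-specific linear calibration.

Pixels qualify for analysis only when their asymmetry is positive and
increases with saturation power; everything else is rejected with a coded
reason rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

__all__ = [
    "ZSpectrumStack",
    "MTRasymMap",
    "RPMMap",
    "QCMask",
    "CalibrationLine",
    "PHMap",
    "ProcessResult",
    "REASON_PASS",
    "REASON_NONPOSITIVE",
    "REASON_NOT_INCREASING",
    "REASON_INVALID",
    "BUILTIN_CALIBRATIONS",
    "ppm_to_hz",
    "smooth_offset_images",
    "interpolate_spectrum",
    "b0_correct_pixel",
    "mtr_asym",
    "rpm",
    "qc_filter",
    "ph_from_rpm",
    "fit_calibration",
    "process_volume",
]

# QC reason codes
REASON_PASS = 0            # adequate CEST effect
REASON_NONPOSITIVE = 1     # MTRasym <= 0 at either power
REASON_NOT_INCREASING = 2  # asymmetry not increasing with power (noise)
REASON_INVALID = 3         # invalid B0 / reference / out-of-range query

#: Spectral extrapolation margin allowed beyond the sampled offsets (Hz);
#: one offset step.
EXTRAP_MARGIN_HZ = 40.0

#: Largest B0 shift (Hz) the spectral correction will apply (3 offset steps).
DEFAULT_B0_LIMIT_HZ = 120.0


def ppm_to_hz(ppm: float, water_frequency_mhz: float) -> float:
    """Chemical-shift offset in Hz at the given water frequency."""
    if water_frequency_mhz <= 0:
        raise ValueError("water_frequency_mhz must be positive")
    return ppm * water_frequency_mhz


@dataclass
class ZSpectrumStack:
    """Multi-offset, multi-power CEST stack plus the unsaturated reference.

    ``channels[i] = (offset_hz, b1_ut)`` describes ``signals[..., i]``.
    """

    signals: np.ndarray                  # (x, y, z, n_channels)
    channels: list[tuple[float, float]]
    reference: np.ndarray                # (x, y, z), I0
    water_frequency_mhz: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.signals.ndim != 4:
            raise ValueError("signals must be a 4-D array")
        if self.signals.shape[-1] != len(self.channels):
            raise ValueError("channel table length must match the 4th dimension")
        if self.reference.shape != self.signals.shape[:3]:
            raise ValueError("reference shape must match the volume shape")
        chans = set(self.channels)
        for f, b1 in self.channels:
            if (-f, b1) not in chans:
                raise ValueError(
                    f"offset {f:+.1f} Hz at {b1} uT has no {-f:+.1f} Hz partner"
                )

    @property
    def b1_powers(self) -> tuple[float, ...]:
        return tuple(sorted({b1 for _, b1 in self.channels}))

    def side(self, b1: float, positive: bool) -> tuple[np.ndarray, np.ndarray]:
        """Sorted offsets and the matching signal volumes of one spectral side."""
        idx = [i for i, (f, b) in enumerate(self.channels)
               if b == b1 and (f > 0) == positive]
        if not idx:
            raise ValueError(f"no channels at b1 = {b1} uT on that side")
        offs = np.array([self.channels[i][0] for i in idx])
        order = np.argsort(offs)
        return offs[order], self.signals[..., [idx[o] for o in order]]


@dataclass
class MTRasymMap:
    value: np.ndarray
    b1: float
    analysis_offset_ppm: float


@dataclass
class RPMMap:
    value: np.ndarray


@dataclass
class QCMask:
    passed: np.ndarray        # bool
    reject_reason: np.ndarray  # int codes, 0 = pass

    def __post_init__(self) -> None:
        if not np.array_equal(self.passed, self.reject_reason == REASON_PASS):
            raise ValueError("passed must be exactly reject_reason == 0")

    def counts(self) -> dict[int, int]:
        codes, n = np.unique(self.reject_reason, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, n)}


@dataclass(frozen=True)
class CalibrationLine:
    """Linear RPM-pH map, ``RPM = slope * pH - intercept``.

    Inverted as ``pH = (RPM + intercept) / slope``; ``valid_ph_range`` is
    the span the line was established over.
    """

    agent: str
    slope: float
    intercept: float
    valid_ph_range: tuple[float, float] = (6.2, 7.8)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def rpm_from_ph(self, ph):
        return self.slope * np.asarray(ph, dtype=float) - self.intercept

    def ph_from_rpm(self, rpm_value):
        return (np.asarray(rpm_value, dtype=float) + self.intercept) / self.slope


#: Published phantom calibrations: iopamidol pH = (RPM + 10.21)/1.88 at
#: +4.2 ppm, iohexol pH = (RPM + 8.39)/1.56 at +4.3 ppm.
BUILTIN_CALIBRATIONS = {
    "iopamidol": CalibrationLine("iopamidol", 1.88, 10.21),
    "iohexol": CalibrationLine("iohexol", 1.56, 8.39),
}

ANALYSIS_OFFSETS_PPM = {"iopamidol": 4.2, "iohexol": 4.3}


@dataclass
class PHMap:
    ph: np.ndarray
    clipped_mask: np.ndarray  # True where outside the calibration range


@dataclass
class ProcessResult:
    """Everything :func:`process_volume` computes for one stack."""

    ph_map: PHMap
    qc: QCMask
    mtr_maps: list[MTRasymMap]
    rpm_map: RPMMap
    n_slices: int
    rejection_counts: dict[int, int]
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations


def smooth_offset_images(stack: ZSpectrumStack, sigma: float) -> ZSpectrumStack:
    """In-plane Gaussian smoothing of every offset image (and the reference).

    ``sigma`` is in voxels; 0 is the identity.  Smoothing is 2-D within each
    slice: through-slice resolution is much coarser than in-plane.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return stack
    sig = gaussian_filter(stack.signals, sigma=(sigma, sigma, 0, 0))
    ref = gaussian_filter(stack.reference, sigma=(sigma, sigma, 0))
    return ZSpectrumStack(sig, list(stack.channels), ref,
                          stack.water_frequency_mhz, stack.affine)


def _check_query_range(offsets: np.ndarray, query: float) -> None:
    lo = offsets.min() - EXTRAP_MARGIN_HZ
    hi = offsets.max() + EXTRAP_MARGIN_HZ
    if not lo <= query <= hi:
        raise ValueError(
            f"query {query:.1f} Hz outside the interpolable range "
            f"[{lo:.1f}, {hi:.1f}] Hz"
        )


def interpolate_spectrum(offsets_hz, signals, query_hz: float) -> float:
    """Natural-cubic-spline value of one spectral side at ``query_hz``.

    Exact at the sampled offsets; queries may extrapolate at most one offset
    step beyond the sampled range.
    """
    offsets = np.asarray(offsets_hz, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if offsets.size < 4:
        raise ValueError("need at least 4 samples per spectral side")
    order = np.argsort(offsets)
    offsets, signals = offsets[order], signals[order]
    _check_query_range(offsets, query_hz)
    spl = CubicSpline(offsets, signals, bc_type="natural", extrapolate=True)
    return float(spl(query_hz))


def b0_correct_pixel(
    offsets_hz,
    signals,
    delta_f_hz: float,
    b0_limit_hz: float = DEFAULT_B0_LIMIT_HZ,
) -> np.ndarray:
    """Re-center one spectral side: value at nominal ``f`` read at ``f + delta_f``.

    A voxel off-resonant by ``delta_f`` records its true spectrum displaced
    by ``delta_f``; evaluating the measured spectrum at the shifted abscissa
    restores the nominal offset grid.  Shifts beyond ``b0_limit_hz`` are
    refused (the caller marks the voxel invalid, reason 3).
    """
    if abs(delta_f_hz) > b0_limit_hz:
        raise ValueError(
            f"B0 shift {delta_f_hz:.1f} Hz exceeds the correction limit "
            f"{b0_limit_hz:.1f} Hz"
        )
    offsets = np.asarray(offsets_hz, dtype=float)
    if delta_f_hz == 0:
        return np.asarray(signals, dtype=float).copy()
    return np.array([
        interpolate_spectrum(offsets, signals, f + delta_f_hz) for f in offsets
    ])


def mtr_asym(i_neg: float, i_pos: float, i0: float) -> float:
    """Asymmetry ``(I(-dw) - I(+dw)) / I0`` of B0-corrected intensities."""
    if i0 <= 0:
        raise ValueError("reference intensity I0 must be positive")
    return (i_neg - i_pos) / i0


def rpm(mtr_rf1: float, mtr_rf2: float) -> float:
    """Ratiometric power mismatch of the low- (RF1) and high-power (RF2) asymmetry."""
    for m in (mtr_rf1, mtr_rf2):
        if not 0 < m < 1:
            raise ValueError("MTRasym values must lie in (0, 1) for RPM; "
                             "such voxels are QC-rejected upstream")
    return ((1.0 - mtr_rf1) / mtr_rf1) / ((1.0 - mtr_rf2) / mtr_rf2)


def qc_filter(mtr_rf1: float, mtr_rf2: float, b0_valid: bool = True) -> tuple[bool, int]:
    """Adequate-CEST-effect rule: positive and increasing with power.

    Returns (passed, reason).  Invalid B0/reference dominates; then
    non-positive asymmetry; then non-increasing asymmetry.
    """
    if not b0_valid:
        return False, REASON_INVALID
    if mtr_rf1 <= 0 or mtr_rf2 <= 0:
        return False, REASON_NONPOSITIVE
    if mtr_rf2 <= mtr_rf1:
        return False, REASON_NOT_INCREASING
    return True, REASON_PASS


def ph_from_rpm(rpm_value: float, line: CalibrationLine) -> tuple[float, bool]:
    """pH from RPM via the line; flags (not censors) out-of-range values."""
    if not np.isfinite(rpm_value):
        raise ValueError("rpm_value must be finite")
    ph = float(line.ph_from_rpm(rpm_value))
    lo, hi = line.valid_ph_range
    return ph, not lo <= ph <= hi


def fit_calibration(rpm_values, known_ph_values, agent: str) -> CalibrationLine:
    """Least-squares line ``RPM = a*pH - b`` through phantom measurements.

    Needs at least three distinct pH levels and a positive fitted slope
    (RPM must increase with pH for the line to be invertible).
    """
    rpm_v = np.asarray(rpm_values, dtype=float)
    ph_v = np.asarray(known_ph_values, dtype=float)
    if rpm_v.shape != ph_v.shape or rpm_v.ndim != 1:
        raise ValueError("rpm_values and known_ph_values must be equal-length 1-D")
    if np.unique(ph_v).size < 3:
        raise ValueError("calibration needs at least 3 distinct pH levels")
    a, c = np.polyfit(ph_v, rpm_v, 1)
    if a <= 0:
        raise ValueError(
            f"fitted calibration slope {a:.4g} is not positive; RPM is not "
            "increasing over the fitted pH range (check saturation powers "
            "and QC pass rates)"
        )
    return CalibrationLine(agent=agent, slope=float(a), intercept=float(-c),
                           valid_ph_range=(float(ph_v.min()), float(ph_v.max())))


# ---------------------------------------------------------------------------
# vectorized spline evaluation used by process_volume


def _batched_spline_eval(
    knots: np.ndarray, values: np.ndarray, queries: np.ndarray
) -> np.ndarray:
    """Evaluate per-column natural cubic splines at per-column query points.

    ``knots``: (K,) shared abscissae; ``values``: (K, N) one spectrum per
    column; ``queries``: (N,).  Columns share knots, so the spline
    coefficients are computed in one vectorized pass.
    """
    spl = CubicSpline(knots, values, axis=0, bc_type="natural")
    c = spl.c  # (4, K-1, N)
    idx = np.clip(np.searchsorted(knots, queries) - 1, 0, knots.size - 2)
    t = queries - knots[idx]
    cols = np.arange(values.shape[1])
    out = c[0, idx, cols]
    for k in range(1, 4):
        out = out * t + c[k, idx, cols]
    return out


# ---------------------------------------------------------------------------
# the full per-volume chain


def process_volume(
    stack: ZSpectrumStack,
    b0_map,
    line: CalibrationLine | dict[int, CalibrationLine],
    sigma: float = 1.0,
    analysis_offset_ppm: float | None = None,
    agent: str | None = None,
    b0_limit_hz: float = DEFAULT_B0_LIMIT_HZ,
    labels: np.ndarray | None = None,
) -> ProcessResult:
    """Run the full per-pixel chain on one stack.

    Order: Gaussian smoothing of every offset image, then per pixel a
    spectral-spline evaluation of both sides at the B0-shifted analysis
    offset, asymmetry at each of the two powers, the QC rule, RPM, and the
    linear pH calibration.  ``line`` may be a single agent calibration or a
    per-tissue-label mapping (then ``labels`` is required and voxels of
    unlisted labels stay uncalibrated).

    ``b0_map`` is a :class:`acidocest.b0.DeltaB0Map` (or any object with
    ``delta_f_hz`` and ``valid`` arrays of the volume shape).
    """
    shape = stack.signals.shape[:3]
    if b0_map.delta_f_hz.shape != shape:
        raise ValueError("B0 map shape does not match the stack")
    if isinstance(line, dict):
        if labels is None:
            raise ValueError("per-label calibration requires a labels volume")
        if labels.shape != shape:
            raise ValueError("labels shape does not match the stack")
    powers = stack.b1_powers
    if len(powers) != 2:
        raise ValueError(
            f"the ratiometric chain needs exactly 2 powers, got {powers}"
        )
    if analysis_offset_ppm is None:
        if agent is None:
            raise ValueError("give analysis_offset_ppm or agent")
        analysis_offset_ppm = ANALYSIS_OFFSETS_PPM[agent]
    f_a = ppm_to_hz(analysis_offset_ppm, stack.water_frequency_mhz)
    for b1 in powers:
        for positive in (True, False):
            offs, _ = stack.side(b1, positive)
            _check_query_range(offs, f_a if positive else -f_a)

    sm = smooth_offset_images(stack, sigma)
    delta_f = b0_map.delta_f_hz
    n_vox = int(np.prod(shape))

    valid = np.asarray(b0_map.valid, dtype=bool) & (sm.reference > 0) \
        & (np.abs(delta_f) <= b0_limit_hz)
    # queries must stay inside the interpolable range on both sides
    for b1 in powers:
        for sign, positive in ((+1, True), (-1, False)):
            offs, _ = stack.side(b1, positive)
            q = sign * f_a + delta_f
            valid &= (q >= offs.min() - EXTRAP_MARGIN_HZ) \
                & (q <= offs.max() + EXTRAP_MARGIN_HZ)

    dflat = delta_f.reshape(-1)
    mtr = {}
    for b1 in powers:
        intens = {}
        for sign, positive in ((+1, True), (-1, False)):
            offs, vols = sm.side(b1, positive)
            vals = vols.reshape(n_vox, offs.size).T  # (K, N)
            intens[sign] = _batched_spline_eval(offs, vals, sign * f_a + dflat)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = (intens[-1] - intens[+1]) / sm.reference.reshape(-1)
        mtr[b1] = m.reshape(shape)

    m1, m2 = mtr[powers[0]], mtr[powers[1]]
    reason = np.full(shape, REASON_PASS, dtype=np.int8)
    reason[(m1 <= 0) | (m2 <= 0)] = REASON_NONPOSITIVE
    reason[(m1 > 0) & (m2 > 0) & (m2 <= m1)] = REASON_NOT_INCREASING
    reason[~valid] = REASON_INVALID
    passed = reason == REASON_PASS
    qc = QCMask(passed=passed, reject_reason=reason)

    rpm_map = np.full(shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpm_all = ((1.0 - m1) / m1) / ((1.0 - m2) / m2)
    rpm_map[passed] = rpm_all[passed]

    ph = np.full(shape, np.nan)
    clipped = np.zeros(shape, dtype=bool)
    if isinstance(line, dict):
        for lab, ln in line.items():
            sel = passed & (labels == lab)
            ph[sel] = ln.ph_from_rpm(rpm_map[sel])
            lo, hi = ln.valid_ph_range
            clipped[sel] = (ph[sel] < lo) | (ph[sel] > hi)
    else:
        ph[passed] = line.ph_from_rpm(rpm_map[passed])
        lo, hi = line.valid_ph_range
        clipped[passed] = (ph[passed] < lo) | (ph[passed] > hi)

    return ProcessResult(
        ph_map=PHMap(ph=ph, clipped_mask=clipped),
        qc=qc,
        mtr_maps=[MTRasymMap(m1, powers[0], analysis_offset_ppm),
                  MTRasymMap(m2, powers[1], analysis_offset_ppm)],
        rpm_map=RPMMap(rpm_map),
        n_slices=shape[2],
        rejection_counts=qc.counts(),
        parameters={
            "sigma": sigma,
            "analysis_offset_ppm": analysis_offset_ppm,
            "b0_limit_hz": b0_limit_hz,
            "b1_powers": list(powers),
        },
    )
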
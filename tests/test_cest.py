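"""Per-pixel processing chain: smoothing, interpolation, B0 correction,
asymmetry, RPM, QC and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from acidocest.cest import (
    BUILTIN_CALIBRATIONS,
    REASON_INVALID,
    REASON_NONPOSITIVE,
    REASON_NOT_INCREASING,
    CalibrationLine,
    ZSpectrumStack,
    b0_correct_pixel,
    fit_calibration,
    interpolate_spectrum,
    mtr_asym,
    ph_from_rpm,
    ppm_to_hz,
    qc_filter,
    rpm,
    smooth_offset_images,
)

OFFSETS = np.arange(430.0, 671.0, 40.0)


class TestPpmToHz:
    def test_zero_is_zero(self):
        assert ppm_to_hz(0.0, 127.731) == 0.0

    def test_agent_offsets_fall_in_sampled_band(self):
        assert ppm_to_hz(4.3, 127.731) == pytest.approx(549.2, abs=0.1)
        hz = ppm_to_hz(4.2, 127.731)
        assert hz == pytest.approx(536.5, abs=0.1)
        assert 430.0 <= hz <= 670.0


class TestSmoothing:
    def _stack(self, signals):
        nchan = signals.shape[-1]
        chans = [(430.0 + 40 * (i // 2), 0.54) for i in range(0, nchan, 2)]
        channels = []
        for f, b1 in chans:
            channels += [(f, b1), (-f, b1)]
        return ZSpectrumStack(signals, channels[:nchan],
                              np.ones(signals.shape[:3]), 127.731)

    def test_sigma_zero_is_identity(self):
        sig = np.random.default_rng(0).random((8, 8, 2, 4))
        stack = self._stack(sig)
        out = smooth_offset_images(stack, 0.0)
        assert out.signals is sig

    def test_constant_volume_unchanged(self):
        stack = self._stack(np.full((8, 8, 2, 4), 0.7))
        out = smooth_offset_images(stack, 1.5)
        assert np.allclose(out.signals, 0.7)

    def test_impulse_matches_direct_convolution(self):
        sig = np.zeros((15, 15, 1, 2))
        sig[7, 7, 0, :] = 1.0
        stack = self._stack(sig)
        out = smooth_offset_images(stack, 1.0)
        want = gaussian_filter(sig[:, :, 0, 0], 1.0)
        assert np.allclose(out.signals[:, :, 0, 0], want, atol=1e-12)
        # smoothing is strictly in-plane: the empty slice stays empty
        assert np.all(out.signals[:, :, 0, :] >= 0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_offset_images(self._stack(np.zeros((4, 4, 1, 2))), -1.0)


class TestInterpolation:
    def test_exact_at_sample_points(self):
        rng = np.random.default_rng(1)
        vals = rng.random(OFFSETS.size)
        for f, v in zip(OFFSETS, vals):
            assert interpolate_spectrum(OFFSETS, vals, f) == pytest.approx(v)

    def test_reproduces_linear_ramp(self):
        vals = 0.001 * OFFSETS + 0.2
        mid = 0.5 * (OFFSETS[2] + OFFSETS[3])
        want = 0.5 * (vals[2] + vals[3])
        assert interpolate_spectrum(OFFSETS, vals, mid) == pytest.approx(want)

    def test_tracks_smooth_function_between_knots(self):
        f = lambda x: 0.6 + 0.3 * np.sin(x / 120.0)
        dense = np.arange(430.0, 671.0, 10.0)
        vals = f(dense)
        for q in np.linspace(440.0, 660.0, 23):
            assert interpolate_spectrum(dense, vals, q) == pytest.approx(
                f(q), rel=1e-3)

    def test_query_beyond_margin_rejected(self):
        with pytest.raises(ValueError, match="interpolable"):
            interpolate_spectrum(OFFSETS, np.ones_like(OFFSETS), 720.0)

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            interpolate_spectrum([430, 470, 510], [1, 1, 1], 450.0)


class TestB0Correction:
    def test_zero_shift_is_identity(self):
        vals = np.random.default_rng(2).random(OFFSETS.size)
        out = b0_correct_pixel(OFFSETS, vals, 0.0)
        assert np.array_equal(out, vals)

    def test_round_trip_recovers_unshifted_spectrum(self):
        f = lambda x: 1.0 - 0.2 * np.exp(-0.5 * ((x - 549.0) / 60.0) ** 2)
        shifted = f(OFFSETS - 40.0)  # voxel off-resonant by +40 Hz
        corrected = b0_correct_pixel(OFFSETS, shifted, 40.0)
        want = f(OFFSETS)
        inner = slice(1, -1)  # spline edges extrapolate one step
        assert np.allclose(corrected[inner], want[inner], atol=1e-3)

    def test_shift_beyond_limit_rejected(self):
        with pytest.raises(ValueError, match="limit"):
            b0_correct_pixel(OFFSETS, np.ones_like(OFFSETS), 200.0)


class TestAsymmetryAndRPM:
    def test_symmetric_spectrum_has_zero_asymmetry(self):
        assert mtr_asym(0.8, 0.8, 1.0) == 0.0

    def test_worked_example(self):
        assert mtr_asym(0.80, 0.70, 1.0) == pytest.approx(0.10)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        base = mtr_asym(0.8, 0.7, 1.0)
        assert mtr_asym(0.8 * c, 0.7 * c, c) == pytest.approx(base, rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mtr_asym(0.8, 0.7, 0.0)

    def test_rpm_identity_when_powers_agree(self):
        assert rpm(0.2, 0.2) == pytest.approx(1.0)

    def test_rpm_hand_values(self):
        assert rpm(0.05, 0.10) == pytest.approx(19.0 / 9.0)
        assert rpm(1.0 / 3.0, 0.5) == pytest.approx(2.0)

    @pytest.mark.parametrize("m1,m2", [(0.0, 0.1), (-0.1, 0.2), (1.0, 0.5)])
    def test_rpm_undefined_outside_unit_interval(self, m1, m2):
        with pytest.raises(ValueError):
            rpm(m1, m2)


class TestQCFilter:
    def test_positive_increasing_passes(self):
        assert qc_filter(0.05, 0.10, True) == (True, 0)

    def test_decreasing_with_power_is_noise(self):
        assert qc_filter(0.10, 0.05, True) == (False, REASON_NOT_INCREASING)

    def test_nonpositive_asymmetry_rejected(self):
        assert qc_filter(-0.02, 0.01, True) == (False, REASON_NONPOSITIVE)

    def test_invalid_b0_dominates(self):
        assert qc_filter(0.05, 0.10, False) == (False, REASON_INVALID)


class TestCalibration:
    def test_published_lines_map_rpm_to_neutral_ph(self):
        ph, clipped = ph_from_rpm(2.95, BUILTIN_CALIBRATIONS["iopamidol"])
        assert ph == pytest.approx((2.95 + 10.21) / 1.88)
        assert ph == pytest.approx(7.00, abs=0.005)
        assert not clipped
        ph, clipped = ph_from_rpm(2.53, BUILTIN_CALIBRATIONS["iohexol"])
        assert ph == pytest.approx(7.00, abs=0.005)
        assert not clipped

    def test_out_of_range_ph_flagged_not_censored(self):
        ph, clipped = ph_from_rpm(-5.0, BUILTIN_CALIBRATIONS["iohexol"])
        assert clipped
        assert np.isfinite(ph)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(min_value=5.5, max_value=8.5))
    def test_line_round_trip_is_identity(self, ph):
        line = BUILTIN_CALIBRATIONS["iopamidol"]
        back, _ = ph_from_rpm(float(line.rpm_from_ph(ph)), line)
        assert back == pytest.approx(ph, abs=1e-12)

    def test_fit_recovers_exact_line(self):
        ph = np.array([6.2, 6.6, 7.0, 7.4, 7.8])
        rpm_v = 1.88 * ph - 10.21
        line = fit_calibration(rpm_v, ph, "iopamidol")
        assert line.slope == pytest.approx(1.88, abs=1e-12)
        assert line.intercept == pytest.approx(10.21, abs=1e-10)

    def test_fit_requires_three_distinct_levels(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration([1.0, 1.1, 2.0, 2.1], [6.2, 6.2, 7.8, 7.8],
                            "iohexol")

    def test_fit_rejects_nonpositive_slope(self):
        ph = np.array([6.2, 7.0, 7.8])
        with pytest.raises(ValueError, match="slope"):
            fit_calibration(-1.0 * ph + 10, ph, "iohexol")

    def test_line_requires_positive_slope(self):
        with pytest.raises(ValueError):
            CalibrationLine("iohexol", -1.0, 0.0)
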
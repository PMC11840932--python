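"""Baseline correction, second derivatives, peak picking and matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftirbind.preprocess import (
    PeakShift,
    baseline_correct,
    confirm_disappearance,
    detect_peaks,
    difference_spectrum,
    match_peaks,
    second_derivative,
)
from ftirbind.spectrum import Spectrum
from ftirbind.synthetic_spectra import (
    FAR_IR,
    Band,
    BandLibrary,
    SimConfig,
    generate_spectrum,
)

from conftest import detect_bands


def _gaussian_spectrum(centers, amps, fwhm=12.0, lo=100.0, hi=700.0, step=1.0,
                       baseline=None):
    nu = np.arange(lo, hi + step / 2, step)
    y = np.zeros_like(nu)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((nu - c) / sigma) ** 2)
    if baseline is not None:
        y += baseline(nu)
    return Spectrum(nu, y)


class TestBaseline:
    def test_pure_linear_ramp_removed(self):
        nu = np.arange(100.0, 700.0)
        spec = Spectrum(nu, 0.01 * nu - 2.0)
        out = baseline_correct(spec, degree=1)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_band_on_ramp_apex_preserved(self):
        clean = _gaussian_spectrum([400.0], [1.0])
        ramped = _gaussian_spectrum([400.0], [1.0], baseline=lambda nu: 0.002 * nu + 0.3)
        corrected = baseline_correct(ramped, degree=1)
        apex_clean = clean.intensities.max()
        apex_corr = corrected.intensities.max()
        assert apex_corr == pytest.approx(apex_clean, rel=0.01)

    def test_idempotent_on_corrected_spectrum(self):
        spec = _gaussian_spectrum([400.0], [1.0])
        once = baseline_correct(spec, degree=1)
        twice = baseline_correct(once, degree=1)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-6)

    def test_too_short_spectrum_rejected(self):
        spec = Spectrum(np.array([1.0, 2.0]), np.zeros(2))
        with pytest.raises(ValueError, match="points"):
            baseline_correct(spec, degree=1)


class TestSecondDerivative:
    def test_line_maps_to_zero(self):
        nu = np.arange(100.0, 700.0)
        spec = Spectrum(nu, 0.5 * nu + 3.0)
        out = second_derivative(spec, 11, 3)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_gaussian_minimum_at_center(self):
        spec = _gaussian_spectrum([362.0], [1.0])
        out = second_derivative(spec, 11, 3)
        nu_min = spec.wavenumbers[np.argmin(out.intensities)]
        assert abs(nu_min - 362.0) <= 1.0

    def test_two_overlapping_gaussians_resolved(self):
        spec = _gaussian_spectrum([362.0, 392.0], [1.0, 1.0], fwhm=15.0)
        out = second_derivative(spec, 11, 3)
        peaks = detect_peaks(out, 0.2, (330, 420))
        assert len(peaks) == 2
        np.testing.assert_allclose(sorted(peaks.centers), [362.0, 392.0], atol=1.0)

    def test_linearity(self):
        f = _gaussian_spectrum([362.0], [1.0])
        g = _gaussian_spectrum([420.0], [0.5])
        combo = Spectrum(f.wavenumbers, 2.0 * f.intensities + 3.0 * g.intensities)
        d_combo = second_derivative(combo, 11, 3).intensities
        d_parts = (
            2.0 * second_derivative(f, 11, 3).intensities
            + 3.0 * second_derivative(g, 11, 3).intensities
        )
        np.testing.assert_allclose(d_combo, d_parts, atol=1e-9)

    @pytest.mark.parametrize("window,order", [(10, 3), (3, 3), (11, 1)])
    def test_invalid_savgol_params(self, window, order):
        spec = _gaussian_spectrum([362.0], [1.0])
        with pytest.raises(ValueError):
            second_derivative(spec, window, order)


class TestDetectPeaks:
    def test_flat_spectrum_no_peaks(self):
        spec = Spectrum(np.arange(100.0, 700.0), np.zeros(600))
        assert len(detect_peaks(spec, 0.35)) == 0

    def test_four_fe_s_peaks(self, far_peaks_native):
        peaks, _ = far_peaks_native
        assert len(peaks) == 4
        np.testing.assert_allclose(
            sorted(peaks.centers), [326.0, 362.0, 392.0, 443.0], atol=1.0
        )

    def test_single_band_single_peak(self):
        spec = _gaussian_spectrum([400.0], [1.0])
        deriv = second_derivative(spec, 11, 3)
        peaks = detect_peaks(deriv, 0.35)
        assert len(peaks) == 1
        assert peaks.centers[0] == pytest.approx(400.0, abs=0.5)

    def test_empty_window_rejected(self):
        spec = _gaussian_spectrum([400.0], [1.0])
        deriv = second_derivative(spec, 11, 3)
        with pytest.raises(ValueError, match="window"):
            detect_peaks(deriv, 0.35, (900.0, 950.0))

    def test_baseline_invariance(self, far_library, far_config):
        """Detection is unchanged by any degree<=1 baseline added pre-correction."""
        spec = generate_spectrum(far_library, "EndoIII", far_config)
        tilted = spec.copy()
        tilted.intensities = spec.intensities + 0.004 * spec.wavenumbers - 1.0
        p0, _ = detect_bands(spec, window=(300, 460))
        p1, _ = detect_bands(tilted, window=(300, 460))
        np.testing.assert_allclose(p0.centers, p1.centers, atol=1e-6)


class TestMatchPeaks:
    def test_identical_lists_unchanged(self):
        shifts = match_peaks([326.0, 362.0], [326.0, 362.0], tol=20.0)
        assert all(s.status == "unchanged" for s in shifts)
        assert all(s.delta_nu == 0.0 for s in shifts)

    def test_thiolate_downshift(self):
        shifts = match_peaks([362.0], [352.0], tol=20.0)
        assert len(shifts) == 1
        assert shifts[0].status == "shifted"
        assert shifts[0].delta_nu == pytest.approx(10.0)

    def test_unmatched_native_disappears(self):
        shifts = match_peaks([890.0], [], tol=20.0)
        assert shifts[0].status == "disappeared"
        assert shifts[0].nu is None

    def test_unmatched_complex_is_new(self):
        shifts = match_peaks([], [500.0], tol=20.0)
        assert shifts[0].status == "new"
        assert shifts[0].nu0 is None

    def test_ambiguous_pairing_prefers_smaller_shift(self):
        # native 360 could match 352 or 365; 365 is closer
        shifts = match_peaks([360.0], [352.0, 365.0], tol=20.0)
        matched = [s for s in shifts if s.status in ("shifted", "unchanged")]
        assert matched[0].nu == 365.0

    @settings(deadline=None, max_examples=50)
    @given(
        nat=st.lists(st.floats(100, 700), max_size=6, unique=True),
        cpx=st.lists(st.floats(100, 700), max_size=6, unique=True),
    )
    def test_count_conservation(self, nat, cpx):
        shifts = match_peaks(sorted(nat), sorted(cpx), tol=15.0)
        matched = sum(1 for s in shifts if s.status in ("shifted", "unchanged"))
        disappeared = sum(1 for s in shifts if s.status == "disappeared")
        new = sum(1 for s in shifts if s.status == "new")
        assert matched + disappeared == len(nat)
        assert matched + new == len(cpx)

    def test_nonpositive_tol_rejected(self):
        with pytest.raises(ValueError, match="tol"):
            match_peaks([362.0], [352.0], tol=0.0)


class TestDifferenceSpectrum:
    def test_self_difference_zero(self):
        spec = _gaussian_spectrum([400.0], [1.0])
        out = difference_spectrum(spec, spec)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_band_plus_baseline_minus_baseline(self):
        base = lambda nu: 0.001 * nu + 0.2
        with_band = _gaussian_spectrum([400.0], [1.0], baseline=base)
        baseline_only = _gaussian_spectrum([], [], baseline=base)
        pure = _gaussian_spectrum([400.0], [1.0])
        out = difference_spectrum(with_band, baseline_only)
        np.testing.assert_allclose(out.intensities, pure.intensities, atol=1e-9)

    def test_grid_mismatch_rejected(self):
        a = _gaussian_spectrum([400.0], [1.0], step=1.0)
        b = _gaussian_spectrum([400.0], [1.0], step=2.0)
        with pytest.raises(ValueError, match="grids"):
            difference_spectrum(a, b)

    def test_complex_minus_native_peaks_at_thiolate(self, far_library, far_config_noiseless):
        native = generate_spectrum(far_library, "EndoIII", far_config_noiseless)
        complex_ = generate_spectrum(far_library, "complex", far_config_noiseless)
        diff = difference_spectrum(complex_, native)
        nu_extreme = diff.wavenumbers[np.argmax(np.abs(diff.intensities))]
        assert 345.0 <= nu_extreme <= 365.0


def test_disappearance_confirmed_on_pipeline_spectra(mid_library, mid_config):
    complex_spec = generate_spectrum(mid_library, "complex", mid_config)
    _, corrected = detect_bands(complex_spec)
    assert confirm_disappearance(corrected, 890.0)
    assert confirm_disappearance(corrected, 967.0)
    assert not confirm_disappearance(corrected, 1055.0)
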
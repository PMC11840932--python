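"""Band library contents, forward-model properties, determinism."""

import math

import numpy as np
import pytest

from ftirbind.synthetic_spectra import (
    FAR_IR,
    MID_IR,
    Band,
    BandLibrary,
    SimConfig,
    band_profile,
    default_band_library,
    default_sim_config,
    forward_from_distances,
    generate_spectrum,
)


class TestDefaultLibrary:
    def test_far_ir_native_fe_s_bands(self, far_library):
        centers = sorted(far_library.centers("EndoIII"))
        assert centers == [326.0, 362.0, 392.0, 443.0]

    def test_far_ir_thiolate_downshift(self, far_library):
        complex_centers = set(far_library.centers("complex"))
        assert 352.0 in complex_centers
        assert 362.0 not in complex_centers

    def test_mid_ir_disappearances(self, mid_library):
        complex_centers = set(mid_library.centers("complex"))
        assert 890.0 not in complex_centers
        assert 967.0 not in complex_centers

    def test_mid_ir_amide_shift(self, mid_library):
        assert 1653.0 in mid_library.centers("EndoIII")
        assert 1650.0 in mid_library.centers("complex")

    def test_1376_split_into_sub_bands(self, mid_library):
        subs = [
            b for b in mid_library.for_species("complex") if b.parent == 1376.0
        ]
        assert len(subs) >= 2
        parent = next(
            b for b in mid_library.for_species("dsDNA") if b.center == 1376.0
        )
        assert all(b.amplitude < parent.amplitude for b in subs)
        assert math.isclose(sum(b.amplitude for b in subs), parent.amplitude)

    def test_complex_bands_traceable(self, mid_library, far_library):
        for lib in (mid_library, far_library):
            native = {b.center for b in lib.bands if b.species != "complex"}
            for b in lib.for_species("complex"):
                assert b.new or b.parent in native

    def test_unknown_range_rejected(self):
        with pytest.raises(ValueError, match="range_label"):
            default_band_library("near-IR")


class TestGenerateSpectrum:
    def test_noiseless_single_gaussian_peak(self):
        band = Band(400.0, 12.0, 0.8, "EndoIII", shape="gaussian")
        lib = BandLibrary((band,), FAR_IR)
        cfg = SimConfig(100.0, 700.0, seed=0, noise_sigma=0.0)
        spec = generate_spectrum(lib, "EndoIII", cfg)
        i = np.argmax(spec.intensities)
        assert spec.wavenumbers[i] == 400.0
        assert spec.intensities[i] == pytest.approx(0.8, abs=1e-12)

    def test_determinism(self, far_library, far_config):
        a = generate_spectrum(far_library, "EndoIII", far_config)
        b = generate_spectrum(far_library, "EndoIII", far_config)
        assert np.array_equal(a.intensities, b.intensities)

    def test_species_get_distinct_noise(self, far_library, far_config):
        a = generate_spectrum(far_library, "EndoIII", far_config)
        b = generate_spectrum(far_library, "complex", far_config)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_gaussian_area_closed_form(self):
        # area of a unit-height gaussian = amplitude*fwhm*sqrt(pi/(4 ln2))
        band = Band(400.0, 12.0, 1.0, "EndoIII", shape="gaussian")
        lib = BandLibrary((band,), FAR_IR)
        cfg = SimConfig(100.0, 700.0, seed=0, grid_step=0.1, noise_sigma=0.0)
        spec = generate_spectrum(lib, "EndoIII", cfg)
        area = np.trapezoid(spec.intensities, spec.wavenumbers)
        expected = 1.0 * 12.0 * math.sqrt(math.pi / (4 * math.log(2)))
        assert area == pytest.approx(expected, rel=1e-3)

    def test_additivity(self):
        b1 = Band(350.0, 12.0, 1.0, "EndoIII")
        b2 = Band(420.0, 12.0, 0.5, "EndoIII")
        cfg = SimConfig(100.0, 700.0, seed=3, noise_sigma=0.0,
                        baseline_coeffs=(0.1, 0.05))
        both = generate_spectrum(BandLibrary((b1, b2), FAR_IR), "EndoIII", cfg)
        single1 = generate_spectrum(BandLibrary((b1,), FAR_IR), "EndoIII", cfg)
        single2 = generate_spectrum(BandLibrary((b2,), FAR_IR), "EndoIII", cfg)
        nu = both.wavenumbers
        # the shared baseline is counted twice in single1 + single2
        x01 = (nu - nu[0]) / (nu[-1] - nu[0])
        baseline = 0.1 + 0.05 * x01
        np.testing.assert_allclose(
            both.intensities,
            single1.intensities + single2.intensities - baseline,
            atol=1e-12,
        )

    def test_band_outside_grid_rejected(self, far_library):
        cfg = SimConfig(500.0, 700.0, seed=0)
        with pytest.raises(ValueError, match="outside grid"):
            generate_spectrum(far_library, "EndoIII", cfg)

    def test_negative_grid_step_rejected(self):
        with pytest.raises(ValueError, match="grid_step"):
            SimConfig(100.0, 700.0, seed=0, grid_step=-1.0)


class TestForwardFromDistances:
    def test_shift_arithmetic(self, far_library):
        cfg = default_sim_config(FAR_IR, seed=0, noise_sigma=0.0)
        native, complex_ = forward_from_distances([7.0], 70.0, far_library, cfg)
        # first tracked band (443) displaced by 70/7 = 10 cm^-1, to 433
        window = (complex_.wavenumbers > 410) & (complex_.wavenumbers < 460)
        nu_win = complex_.wavenumbers[window]
        peak = nu_win[np.argmax(complex_.intensities[window])]
        assert peak == pytest.approx(433.0, abs=1.0)
        native_window = (native.wavenumbers > 410) & (native.wavenumbers < 460)
        native_peak = native.wavenumbers[native_window][
            np.argmax(native.intensities[native_window])
        ]
        assert native_peak == pytest.approx(443.0, abs=1.0)

    def test_infinite_distance_limit(self, far_library):
        cfg = default_sim_config(FAR_IR, seed=0, noise_sigma=0.0)
        native, complex_ = forward_from_distances([1e12], 70.0, far_library, cfg)
        np.testing.assert_allclose(native.intensities, complex_.intensities, atol=1e-9)

    def test_nonpositive_distance_rejected(self, far_library):
        cfg = default_sim_config(FAR_IR, seed=0)
        with pytest.raises(ValueError, match="distances"):
            forward_from_distances([7.0, -1.0], 70.0, far_library, cfg)


@pytest.mark.parametrize("shape,expected_peak", [("gaussian", 1.0),
                                                 ("lorentzian", 1.0),
                                                 ("pseudo_voigt", 1.0)])
def test_lineshape_peak_height(shape, expected_peak):
    band = Band(400.0, 12.0, 1.0, "EndoIII", shape=shape)
    nu = np.linspace(300, 500, 2001)
    profile = band_profile(band, nu)
    assert profile.max() == pytest.approx(expected_peak, abs=1e-9)
    # half maximum reached fwhm apart
    half = profile >= 0.5
    width = nu[half][-1] - nu[half][0]
    assert width == pytest.approx(12.0, abs=0.2)
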
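"""Shared fixtures: band libraries, grids, and a detection helper."""

import numpy as np
import pytest

from ftirbind.preprocess import baseline_correct, detect_peaks, second_derivative
from ftirbind.synthetic_spectra import (
    FAR_IR,
    MID_IR,
    default_band_library,
    default_sim_config,
    generate_spectrum,
)


@pytest.fixture(scope="session")
def far_library():
    return default_band_library(FAR_IR)


@pytest.fixture(scope="session")
def mid_library():
    return default_band_library(MID_IR)


@pytest.fixture
def far_config():
    return default_sim_config(FAR_IR, seed=20)


@pytest.fixture
def far_config_noiseless():
    return default_sim_config(FAR_IR, seed=20, noise_sigma=0.0)


@pytest.fixture
def mid_config():
    return default_sim_config(MID_IR, seed=20)


def detect_bands(spectrum, window=None, prominence_frac=0.35, sg_window=17):
    """Baseline-correct, differentiate and peak-pick one spectrum."""
    corrected = baseline_correct(spectrum, degree=1)
    deriv = second_derivative(corrected, sg_window, 3)
    return detect_peaks(deriv, prominence_frac, window), corrected


@pytest.fixture(scope="session")
def far_peaks_native(far_library):
    spec = generate_spectrum(far_library, "EndoIII", default_sim_config(FAR_IR, seed=20))
    peaks, corrected = detect_bands(spec, window=(300.0, 460.0))
    return peaks, corrected


@pytest.fixture(scope="session")
def far_peaks_complex(far_library):
    spec = generate_spectrum(far_library, "complex", default_sim_config(FAR_IR, seed=20))
    peaks, corrected = detect_bands(spec, window=(300.0, 460.0))
    return peaks, corrected
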
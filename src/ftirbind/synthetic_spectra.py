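"""Synthetic mid-IR and far-IR spectra for dsDNA, EndoIII and their complex.

The generator is the study's stand-in for the instrument: it encodes the
band inventory of the three species — the dsDNA fingerprint bands (720,
780, 782, 890, 967, 1055, 1110, 1213, 1281, 1329, 1376 cm^-1), the
protein amide-I band (1653 cm^-1) and the four far-IR Fe-S stretching
modes of the [4Fe4S] cluster (443, 392, 362, 326 cm^-1) — together with
the documented complex-state edits: the amide-I band downshifts by
3 cm^-1, the Fe-S thiolate mode moves 362 -> 352 cm^-1, the deoxyribose
(890) and O-P-O (967) bands disappear, the 780 and 1055 bands shift by a
few cm^-1, and the 1376 base-vibration band is distorted into two
smaller sub-bands.

Forward model: intensity(nu) = sum of band lineshapes + polynomial
baseline + seeded additive gaussian noise.  Everything is deterministic
given the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .spectrum import Spectrum

__all__ = [
    "Band",
    "BandLibrary",
    "SimConfig",
    "MID_IR",
    "FAR_IR",
    "SPECIES",
    "default_band_library",
    "default_sim_config",
    "band_profile",
    "generate_spectrum",
    "forward_from_distances",
]

MID_IR = "mid-IR"
FAR_IR = "far-IR"
SPECIES = ("dsDNA", "EndoIII", "complex")

#: Spectral windows the default grids cover (cm^-1). The far-IR window is
#: the instrument's 700-100 cm^-1 range; the mid-IR grid is truncated at
#: 1800 cm^-1 since the band inventory ends at the amide-I mode.
_DEFAULT_GRID = {FAR_IR: (100.0, 700.0), MID_IR: (600.0, 1800.0)}

#: Default full widths at half maximum (cm^-1); condensed-phase IR bands,
#: narrower in the far-IR so that the 362/392 pair overlaps enough for
#: second-derivative resolution to matter.
DEFAULT_FWHM = {FAR_IR: 12.0, MID_IR: 20.0}


@dataclass(frozen=True)
class Band:
    """One vibrational band of one species.

    ``parent`` is the native-band center a complex-species band traces
    back to (None for native bands and for genuinely new bands, which
    carry ``new=True``).
    """

    center: float
    fwhm: float
    amplitude: float
    species: str
    assignment: str = ""
    shape: str = "pseudo_voigt"
    eta: float = 0.5
    parent: float | None = None
    new: bool = False

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown lineshape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"pseudo-Voigt mixing eta must be in [0,1], got {self.eta}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")


@dataclass(frozen=True)
class BandLibrary:
    """Ordered band inventory for one spectral range."""

    bands: tuple[Band, ...]
    range_label: str

    def __post_init__(self) -> None:
        if self.range_label not in (MID_IR, FAR_IR):
            raise ValueError(f"unknown range_label {self.range_label!r}")
        seen: set[tuple[str, float]] = set()
        for band in self.bands:
            key = (band.species, band.center)
            if key in seen:
                raise ValueError(
                    f"duplicate band center {band.center} for species {band.species}"
                )
            seen.add(key)
        native = {b.center for b in self.bands if b.species != "complex"}
        for band in self.bands:
            if band.species == "complex" and not band.new:
                if band.parent is None or band.parent not in native:
                    raise ValueError(
                        f"complex band at {band.center} is neither traceable to a "
                        "native band nor flagged new"
                    )

    def for_species(self, species: str) -> tuple[Band, ...]:
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}")
        return tuple(b for b in self.bands if b.species == species)

    def centers(self, species: str) -> np.ndarray:
        return np.array([b.center for b in self.for_species(species)])


@dataclass(frozen=True)
class SimConfig:
    """Grid, noise and baseline settings for the forward model.

    ``noise_sigma=None`` resolves to 1% of the largest band amplitude of
    the species being generated.  ``baseline_coeffs`` are polynomial
    coefficients in ascending degree (degree <= 2) evaluated on a grid
    rescaled to [0, 1] so the magnitudes are comparable across ranges.
    """

    grid_start: float
    grid_end: float
    seed: int
    grid_step: float = 1.0
    noise_sigma: float | None = None
    baseline_coeffs: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.grid_start >= self.grid_end:
            raise ValueError("grid_start must be < grid_end")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.baseline_coeffs) > 3:
            raise ValueError("baseline polynomial degree must be <= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def default_sim_config(range_label: str, seed: int, **overrides) -> SimConfig:
    """Packaged default grid for a spectral range (1 cm^-1 step)."""
    if range_label not in _DEFAULT_GRID:
        raise ValueError(f"unknown range_label {range_label!r}")
    lo, hi = _DEFAULT_GRID[range_label]
    params = dict(grid_start=lo, grid_end=hi, seed=seed)
    params.update(overrides)
    return SimConfig(**params)


def _mid_ir_bands(
    sub_band_offsets: Sequence[float],
    shift_780: float,
    shift_1055: float,
) -> list[Band]:
    """Mid-IR inventory: dsDNA fingerprint + amide-I, and the complex edits."""
    w = DEFAULT_FWHM[MID_IR]
    dsdna = [
        # (center, amplitude, assignment)
        (720.0, 0.60, "CH out-of-plane"),
        (780.0, 0.70, "CH out-of-plane"),
        (782.0, 0.65, "sugar-phosphate"),
        (890.0, 0.50, "deoxyribose ring"),
        (967.0, 0.55, "O-P-O bending"),
        (1055.0, 0.90, "phosphate backbone"),  # alias: 1060 cm^-1
        (1110.0, 0.60, "sugar-phosphate"),
        (1213.0, 0.80, "phosphate stretching"),
        (1281.0, 0.50, "CH2 wagging / N-H deformation"),
        (1329.0, 0.55, "CH2 wagging"),
        (1376.0, 0.70, "C-N base vibration"),
    ]
    bands = [
        Band(c, w, a, "dsDNA", assignment=s) for c, a, s in dsdna
    ]
    bands.append(Band(1653.0, w, 1.00, "EndoIII", assignment="amide-I"))

    complex_edits: list[Band] = []
    for c, a, s in dsdna:
        if c in (890.0, 967.0):
            continue  # disappear upon binding
        if c == 780.0:
            complex_edits.append(
                Band(c - shift_780, w, a, "complex", assignment=s, parent=c)
            )
        elif c == 1055.0:
            complex_edits.append(
                Band(c - shift_1055, w, a, "complex", assignment=s, parent=c)
            )
        elif c == 1376.0:
            for off in sub_band_offsets:  # distorted into smaller sub-bands
                complex_edits.append(
                    Band(
                        c + off,
                        w,
                        a / len(sub_band_offsets),
                        "complex",
                        assignment="C-N base vibration (distorted)",
                        parent=c,
                    )
                )
        else:
            complex_edits.append(
                Band(c, w, a, "complex", assignment=s, parent=c)
            )
    complex_edits.append(
        Band(1650.0, w, 1.00, "complex", assignment="amide-I", parent=1653.0)
    )
    return bands + complex_edits


def _far_ir_bands() -> list[Band]:
    """Far-IR inventory: the four Fe-S cluster modes and the thiolate downshift."""
    w = DEFAULT_FWHM[FAR_IR]
    fes = [
        (443.0, 0.80, "Fe-S"),
        (392.0, 0.90, "Fe-S"),
        (362.0, 1.00, "Fe-S thiolate"),
        (326.0, 0.70, "Fe-S"),
    ]
    bands = [Band(c, w, a, "EndoIII", assignment=s) for c, a, s in fes]
    for c, a, s in fes:
        if c == 362.0:
            # thiolate stretch downshifts 362 -> 352 with a slight intensity loss
            bands.append(
                Band(352.0, w, 0.90, "complex", assignment=s, parent=c)
            )
        else:
            bands.append(Band(c, w, a, "complex", assignment=s, parent=c))
    return bands


def default_band_library(
    range_label: str,
    sub_band_offsets: Sequence[float] = (-6.0, 6.0),
    shift_780: float = 2.0,
    shift_1055: float = 3.0,
) -> BandLibrary:
    """Packaged band inventory for the three species in one spectral range.

    Parameters
    ----------
    range_label:
        ``"mid-IR"`` or ``"far-IR"``.
    sub_band_offsets:
        Offsets (cm^-1) of the sub-bands replacing the 1376 cm^-1 band in
        the complex; amplitude is split equally among them.
    shift_780, shift_1055:
        Downshifts (cm^-1) applied to the 780 and 1055 cm^-1 dsDNA bands
        in the complex.
    """
    if range_label == MID_IR:
        bands = _mid_ir_bands(tuple(sub_band_offsets), shift_780, shift_1055)
    elif range_label == FAR_IR:
        bands = _far_ir_bands()
    else:
        raise ValueError(f"unknown range_label {range_label!r}")
    return BandLibrary(tuple(bands), range_label)


# --- lineshapes -------------------------------------------------------------

def _gaussian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((nu - center) / sigma) ** 2)


def _lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma**2 / ((nu - center) ** 2 + gamma**2)


def band_profile(band: Band, nu: np.ndarray) -> np.ndarray:
    """Evaluate one band's lineshape (peak value = amplitude) on a grid."""
    if band.shape == "gaussian":
        profile = _gaussian(nu, band.center, band.fwhm)
    elif band.shape == "lorentzian":
        profile = _lorentzian(nu, band.center, band.fwhm)
    else:  # pseudo-Voigt: linear mix, eta = lorentzian fraction
        profile = band.eta * _lorentzian(nu, band.center, band.fwhm) + (
            1.0 - band.eta
        ) * _gaussian(nu, band.center, band.fwhm)
    return band.amplitude * profile


_SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}
_RANGE_INDEX = {MID_IR: 0, FAR_IR: 1}


def _noise_rng(config: SimConfig, species: str, range_label: str) -> np.random.Generator:
    # distinct, reproducible streams per (seed, species, range)
    ss = np.random.SeedSequence(
        int(config.seed),
        spawn_key=(_SPECIES_INDEX[species], _RANGE_INDEX[range_label]),
    )
    return np.random.default_rng(ss)


def generate_spectrum(library: BandLibrary, species: str, config: SimConfig) -> Spectrum:
    """Forward-model one species' spectrum from a band library.

    intensity(nu) = sum of lineshapes + baseline polynomial + N(0, sigma)
    noise; bit-identical for identical inputs (species-specific seeded
    noise streams).
    """
    bands = library.for_species(species)
    nu = config.grid()
    for band in bands:
        if not (nu[0] <= band.center <= nu[-1]):
            raise ValueError(
                f"band at {band.center} cm^-1 outside grid "
                f"[{nu[0]}, {nu[-1]}] cm^-1"
            )
    y = np.zeros_like(nu)
    for band in bands:
        y += band_profile(band, nu)

    x01 = (nu - nu[0]) / (nu[-1] - nu[0])
    baseline = np.zeros_like(nu)
    for power, coeff in enumerate(config.baseline_coeffs):
        baseline += coeff * x01**power
    y += baseline

    sigma = config.noise_sigma
    if sigma is None:
        max_amp = max((b.amplitude for b in bands), default=0.0)
        sigma = 0.01 * max_amp
    if sigma > 0:
        y += _noise_rng(config, species, library.range_label).normal(0.0, sigma, nu.size)

    meta = {
        "species": species,
        "range": library.range_label,
        "seed": config.seed,
        "noise_sigma": sigma,
    }
    return Spectrum(nu, y, meta)


def forward_from_distances(
    distances: Iterable[float],
    k: float,
    base_library: BandLibrary,
    config: SimConfig,
) -> tuple[Spectrum, Spectrum]:
    """Build a (native, complex) spectrum pair from known binding distances.

    The i-th tracked band (native bands in library order) is downshifted
    by ``delta_nu_i = k / r_i`` in the complex spectrum — the inverse of
    the shift-to-distance law — so the pair serves parameter-recovery
    tests of the full analysis chain.
    """
    distances = list(distances)
    if any(r <= 0 for r in distances):
        raise ValueError("all distances must be > 0")
    if k <= 0:
        raise ValueError("calibration constant k must be > 0")
    native_bands = tuple(b for b in base_library.bands if b.species != "complex")
    if len(distances) > len(native_bands):
        raise ValueError(
            f"{len(distances)} distances supplied but only "
            f"{len(native_bands)} native bands to track"
        )
    shifted: list[Band] = []
    for i, band in enumerate(native_bands):
        if i < len(distances):
            delta = k / distances[i]
            shifted.append(
                replace(band, center=band.center - delta, species="complex",
                        parent=band.center)
            )
        else:
            shifted.append(replace(band, species="complex", parent=band.center))
    lib = BandLibrary(native_bands + tuple(shifted), base_library.range_label)
    native_species = native_bands[0].species if native_bands else "EndoIII"
    # native spectrum contains every non-complex band regardless of species
    native_lib_species = {b.species for b in native_bands}
    if len(native_lib_species) == 1:
        spec_native = generate_spectrum(lib, native_species, config)
    else:
        # merge species: relabel all native bands to one species for generation
        merged = tuple(replace(b, species="EndoIII") for b in native_bands) + tuple(
            lib.for_species("complex")
        )
        lib = BandLibrary(merged, base_library.range_label)
        spec_native = generate_spectrum(lib, "EndoIII", config)
    spec_complex = generate_spectrum(lib, "complex", config)
    return spec_native, spec_complex
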
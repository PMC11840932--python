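"""Baseline correction, second derivatives, peak detection and band matching.

This reproduces the band-tracking analysis applied to the free-species
and complex spectra: correct the baseline, compute a Savitzky-Golay
second derivative (band centers appear as sharpened minima, resolving
overlapped peaks), pick the minima, and match peaks across the native
and complex spectra to obtain per-band frequency shifts
|nu - nu0|, disappearances and new bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectrum import Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "PeakShift",
    "baseline_correct",
    "second_derivative",
    "detect_peaks",
    "match_peaks",
    "difference_spectrum",
    "estimate_noise",
    "confirm_disappearance",
    "annotate_assignments",
]

#: Matched pairs closer than this (cm^-1) count as unchanged rather than
#: shifted: half the default 1 cm^-1 grid step, below which a detected
#: displacement is indistinguishable from noise wobble.
UNCHANGED_TOL = 0.5


@dataclass(frozen=True)
class Peak:
    center: float
    prominence: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("peak prominence must be > 0")
        lo, hi = self.window
        if not lo <= self.center <= hi:
            raise ValueError(f"peak center {self.center} outside window {self.window}")


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        centers = [p.center for p in self.peaks]
        if centers != sorted(centers):
            raise ValueError("peaks must be sorted by center")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])


@dataclass(frozen=True)
class PeakShift:
    """One matched (or unmatched) band pair between native and complex spectra.

    ``nu0`` is the native center, ``nu`` the complex center; exactly one
    of them is None for status ``disappeared`` / ``new`` respectively.
    """

    assignment: str
    nu0: float | None
    nu: float | None
    delta_nu: float | None
    intensity_change: float | None
    status: str  # shifted | disappeared | new | unchanged

    def __post_init__(self) -> None:
        if self.status not in ("shifted", "disappeared", "new", "unchanged"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "disappeared" and self.nu is not None:
            raise ValueError("disappeared band must have nu=None")
        if self.status == "new" and self.nu0 is not None:
            raise ValueError("new band must have nu0=None")
        if self.status in ("shifted", "unchanged"):
            if self.nu0 is None or self.nu is None:
                raise ValueError(f"{self.status} band needs both nu0 and nu")
            expected = abs(self.nu - self.nu0)
            if self.delta_nu is None or abs(self.delta_nu - expected) > 1e-9:
                raise ValueError("delta_nu must equal |nu - nu0|")


def baseline_correct(
    spectrum: Spectrum,
    degree: int = 1,
    max_rounds: int = 30,
    mask_sigma: float = 2.0,
) -> Spectrum:
    """Subtract an iteratively fitted polynomial baseline.

    A polynomial of the given degree is least-squares fitted, points
    lying more than ``mask_sigma`` residual standard deviations *above*
    the fit (band regions) are masked, and the fit repeats until the mask
    stabilises (at most ``max_rounds`` rounds).  Masking only the
    positive side lets the fit settle on the band-free baseline, so the
    residual over peak-free regions averages to zero and an
    already-corrected spectrum passes through unchanged.
    """
    if degree not in (0, 1, 2):
        raise ValueError("baseline degree must be 0, 1 or 2")
    nu, y = spectrum.wavenumbers, spectrum.intensities
    if nu.size < degree + 2:
        raise ValueError(
            f"spectrum has {nu.size} points; need at least {degree + 2} "
            f"for a degree-{degree} baseline"
        )
    keep = np.ones(nu.size, dtype=bool)
    baseline = np.zeros_like(y)
    for _ in range(max_rounds):
        coeffs = np.polynomial.polynomial.Polynomial.fit(nu[keep], y[keep], degree)
        baseline = coeffs(nu)
        resid = y - baseline
        sigma = float(np.std(resid[keep]))
        if sigma < 1e-12:
            break
        new_keep = resid <= mask_sigma * sigma
        if new_keep.sum() < degree + 2 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    out = spectrum.copy(baseline_degree=degree)
    out.intensities = y - baseline
    return out


def second_derivative(
    spectrum: Spectrum, window_pts: int = 17, poly_order: int = 3
) -> Spectrum:
    """Savitzky-Golay second derivative on the native grid."""
    if window_pts % 2 == 0:
        raise ValueError("window_pts must be odd")
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    if window_pts <= poly_order:
        raise ValueError("window_pts must exceed poly_order")
    if window_pts > len(spectrum):
        raise ValueError("window larger than spectrum")
    d2 = savgol_filter(
        spectrum.intensities,
        window_length=window_pts,
        polyorder=poly_order,
        deriv=2,
        delta=spectrum.step,
    )
    out = spectrum.copy(derivative=2, savgol_window=window_pts, savgol_order=poly_order)
    out.intensities = d2
    return out


def _parabolic_refine(nu: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid minimum via a parabola through three points around index i."""
    if i == 0 or i == y.size - 1:
        return float(nu[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-300:
        return float(nu[i])
    offset = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    step = nu[i + 1] - nu[i] if offset >= 0 else nu[i] - nu[i - 1]
    return float(nu[i] + offset * step)


def detect_peaks(
    second_deriv_spectrum: Spectrum,
    prominence_frac: float = 0.35,
    window: tuple[float, float] | None = None,
) -> PeakList:
    """Pick band centers as minima of a second-derivative spectrum.

    Minima whose prominence is at least ``prominence_frac`` times the
    prominence of the deepest minimum are kept; centers are refined to
    sub-grid precision with a three-point parabola.
    """
    if not 0 < prominence_frac <= 1:
        raise ValueError("prominence_frac must be in (0, 1]")
    nu = second_deriv_spectrum.wavenumbers
    y = second_deriv_spectrum.intensities
    if window is not None:
        lo, hi = window
        sel = (nu >= lo) & (nu <= hi)
        if not sel.any():
            raise ValueError(f"window {window} contains no grid points")
        nu, y = nu[sel], y[sel]
    neg = -y
    idx, props = find_peaks(neg, prominence=0.0)
    if idx.size == 0:
        return PeakList(())
    max_prom = props["prominences"].max()
    if max_prom <= 0:
        return PeakList(())
    keep = props["prominences"] >= prominence_frac * max_prom
    peaks = []
    for i, prom, lb, rb in zip(
        idx[keep],
        props["prominences"][keep],
        props["left_bases"][keep],
        props["right_bases"][keep],
    ):
        center = _parabolic_refine(nu, y, int(i))
        peaks.append(Peak(center, float(prom), (float(nu[lb]), float(nu[rb]))))
    peaks.sort(key=lambda p: p.center)
    return PeakList(tuple(peaks))


def estimate_noise(spectrum: Spectrum) -> float:
    """Robust noise estimate from the median absolute successive difference."""
    diffs = np.diff(spectrum.intensities)
    return float(1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0))


def match_peaks(
    native_peaks: PeakList | Sequence[float],
    complex_peaks: PeakList | Sequence[float],
    tol: float = 20.0,
    native_spectrum: Spectrum | None = None,
    complex_spectrum: Spectrum | None = None,
    unchanged_tol: float = UNCHANGED_TOL,
) -> list[PeakShift]:
    """Greedily match native and complex peaks within ``tol`` cm^-1.

    Candidate pairs are taken in order of smallest displacement (ties:
    lower native wavenumber).  Unmatched native peaks become
    ``disappeared`` — confirmed, when the complex spectrum is supplied,
    by the complex intensity at nu0 lying below 3x the noise level —
    and unmatched complex peaks become ``new``.  When both
    baseline-corrected spectra are supplied, matched pairs carry the
    relative intensity change (I_complex(nu) - I_native(nu0)) / I_native(nu0).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    nat = list(native_peaks.centers if isinstance(native_peaks, PeakList) else native_peaks)
    cpx = list(complex_peaks.centers if isinstance(complex_peaks, PeakList) else complex_peaks)

    candidates = sorted(
        (
            (abs(c - n), n, c, i, j)
            for i, n in enumerate(nat)
            for j, c in enumerate(cpx)
            if abs(c - n) <= tol
        ),
        key=lambda t: (t[0], t[1]),
    )
    used_n: set[int] = set()
    used_c: set[int] = set()
    shifts: list[PeakShift] = []
    for delta, n, c, i, j in candidates:
        if i in used_n or j in used_c:
            continue
        used_n.add(i)
        used_c.add(j)
        change = None
        if native_spectrum is not None and complex_spectrum is not None:
            ref = native_spectrum.intensity_at(n)
            if abs(ref) > 1e-12:
                change = (complex_spectrum.intensity_at(c) - ref) / ref
        status = "unchanged" if delta <= unchanged_tol else "shifted"
        shifts.append(
            PeakShift(
                assignment="",
                nu0=float(n),
                nu=float(c),
                delta_nu=float(delta),
                intensity_change=change,
                status=status,
            )
        )
    for i, n in enumerate(nat):
        if i in used_n:
            continue
        change = None
        if complex_spectrum is not None and native_spectrum is not None:
            # relative intensity change at nu0 (about -1 for a band that
            # truly vanished; the 3x-noise residual check is applied below)
            ref = native_spectrum.intensity_at(n)
            if abs(ref) > 1e-12:
                change = (complex_spectrum.intensity_at(n) - ref) / ref
        shifts.append(
            PeakShift(
                assignment="",
                nu0=float(n),
                nu=None,
                delta_nu=None,
                intensity_change=change,
                status="disappeared",
            )
        )
    for j, c in enumerate(cpx):
        if j in used_c:
            continue
        shifts.append(
            PeakShift(
                assignment="",
                nu0=None,
                nu=float(c),
                delta_nu=None,
                intensity_change=None,
                status="new",
            )
        )
    shifts.sort(key=lambda s: s.nu0 if s.nu0 is not None else s.nu)
    return shifts


def confirm_disappearance(complex_spectrum: Spectrum, nu0: float) -> bool:
    """True if the complex intensity at ``nu0`` is below 3x the noise floor.

    Operational criterion for a genuine band disappearance (as opposed to
    an undetected but still-present band); evaluated on the
    baseline-corrected complex spectrum.
    """
    noise = estimate_noise(complex_spectrum)
    return abs(complex_spectrum.intensity_at(nu0)) < 3.0 * max(noise, 1e-12)


def difference_spectrum(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise sample-minus-background difference on identical grids."""
    if sample.wavenumbers.shape != background.wavenumbers.shape or not np.allclose(
        sample.wavenumbers, background.wavenumbers
    ):
        raise ValueError("grids do not match")
    out = sample.copy(
        difference_of=(
            sample.meta.get("species", "sample"),
            background.meta.get("species", "background"),
        )
    )
    out.intensities = sample.intensities - background.intensities
    return out


def annotate_assignments(
    shifts: Sequence[PeakShift],
    assignments: dict[str, float],
    tol: float = 10.0,
) -> list[PeakShift]:
    """Label shifts with the nearest library band assignment within ``tol``."""
    labelled = []
    for s in shifts:
        anchor = s.nu0 if s.nu0 is not None else s.nu
        best, best_d = "", tol
        for name, center in assignments.items():
            d = abs(center - anchor)
            if d <= best_d:
                best, best_d = name, d
        labelled.append(replace(s, assignment=best))
    return labelled
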
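"""Spectrum container and plain-text I/O.

A spectrum is a strictly ascending wavenumber grid (cm^-1) with one
absorbance value per grid point and a free-form metadata mapping
(species, spectral range, provenance).  Files are two-column CSV with
``# key=value`` header lines, the format every stage of the pipeline
reads and writes.  A minimal JCAMP-DX reader (``XYDATA (X++(Y..Y))``
dialect only) is provided for real instrument exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "read_csv", "write_csv", "read_jcamp"]


@dataclass
class Spectrum:
    """Wavenumber grid + intensities + metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if not (np.all(np.isfinite(self.wavenumbers)) and np.all(np.isfinite(self.intensities))):
            raise ValueError("spectrum contains non-finite values")

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def copy(self, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy(), meta)

    def intensity_at(self, nu: float) -> float:
        """Linearly interpolated intensity at wavenumber ``nu``."""
        return float(np.interp(nu, self.wavenumbers, self.intensities))


def write_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a two-column CSV with ``# key=value`` metadata header lines."""
    path = Path(path)
    lines = []
    for key in ("species", "range", "seed"):
        if key in spectrum.meta:
            lines.append(f"# {key}={spectrum.meta[key]}")
    for key, value in spectrum.meta.items():
        if key not in ("species", "range", "seed"):
            lines.append(f"# {key}={value}")
    lines.append("wavenumber_cm-1,intensity")
    for nu, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{nu:.6g},{y:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_csv(path: str | Path) -> Spectrum:
    """Read the two-column spectral CSV written by :func:`write_csv`."""
    meta: dict = {}
    nus: list[float] = []
    ys: list[float] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if line[0].isalpha() or line.startswith('"'):
            continue  # column header
        parts = line.split(",")
        nus.append(float(parts[0]))
        ys.append(float(parts[1]))
    if not nus:
        raise ValueError(f"no data rows in {path}")
    order = np.argsort(nus)
    return Spectrum(np.asarray(nus)[order], np.asarray(ys)[order], meta)


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX spectrum, ``XYDATA=(X++(Y..Y))`` dialect only.

    Supports the fixed-form variant where each data line starts with an
    X value followed by whitespace-separated Y values; XFACTOR/YFACTOR
    and DELTAX are honoured.  Compressed (SQZ/DIF/DUP) encodings are out
    of scope and raise ``ValueError``.
    """
    text = Path(path).read_text()
    meta: dict = {}
    xfactor = yfactor = 1.0
    deltax = None
    npoints = None
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise ValueError(f"unsupported XYDATA dialect: {value!r}")
                in_data = True
                continue
            if label == "END":
                in_data = False
                continue
            if label == "XFACTOR":
                xfactor = float(value)
            elif label == "YFACTOR":
                yfactor = float(value)
            elif label == "DELTAX":
                deltax = float(value)
            elif label == "NPOINTS":
                npoints = int(float(value))
            elif label in ("TITLE", "XUNITS", "YUNITS", "DATATYPE"):
                meta[label.lower()] = value
            continue
        if in_data:
            tokens = line.replace(",", " ").split()
            if any(c in line for c in "JKLMNOPQR%jk"):
                raise ValueError("compressed JCAMP (SQZ/DIF) encodings not supported")
            x0 = float(tokens[0]) * xfactor
            yvals = [float(t) * yfactor for t in tokens[1:]]
            if deltax is None and len(yvals) > 1:
                raise ValueError("multi-Y lines require ##DELTAX")
            for i, y in enumerate(yvals):
                xs.append(x0 + i * (deltax if deltax is not None else 0.0))
                ys.append(y)
    if not xs:
        raise ValueError(f"no XYDATA found in {path}")
    if npoints is not None and npoints != len(xs):
        raise ValueError(f"NPOINTS={npoints} but parsed {len(xs)} points")
    order = np.argsort(xs)
    return Spectrum(np.asarray(xs)[order], np.asarray(ys)[order], meta)
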
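"""Binding thermodynamics from the dissociation constant.

ΔG = −RT ln Kd (R = 8.314 J/(mol·K)), reported in kJ/mol, and
ΔS = (ΔH − ΔG)·1000/T in J/(mol·K) from the closure ΔG = ΔH − TΔS.

Sign convention: the relations are applied exactly as stated, so a
micromolar Kd (< 1 M) gives a *positive* ΔG — the convention under
which the reported 28.52 kJ/mol at Kd = 10 μM, T = 298 K arises.  Under
the usual association convention (ΔG° = +RT ln Kd for dissociation
written as binding free energy) the sign would flip; ``convention_note``
records this so downstream consumers are not surprised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["R_GAS", "ThermoParams", "ThermoResult", "gibbs_from_kd",
           "entropy_from_gibbs", "compute_thermo"]

#: Universal gas constant, J/(mol·K).
R_GAS = 8.314

_CONVENTION_NOTE = (
    "dG = -R*T*ln(Kd) applied literally: Kd < 1 M yields dG > 0 "
    "(dissociation-direction free energy); dS closes dG = dH - T*dS"
)


@dataclass(frozen=True)
class ThermoParams:
    """Inputs: Kd in molar, T in kelvin, dH in kJ/mol."""

    Kd: float = 1.0e-5
    T: float = 298.0
    dH: float = -30.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if self.T <= 0:
            raise ValueError("T must be > 0")


@dataclass(frozen=True)
class ThermoResult:
    dG: float  # kJ/mol
    dS: float  # J/(mol·K)
    dH: float  # kJ/mol
    T: float  # K
    convention_note: str = _CONVENTION_NOTE

    def __post_init__(self) -> None:
        # unit-consistent closure dG = dH - T*dS/1000
        if abs(self.dG - (self.dH - self.T * self.dS / 1000.0)) > 1e-9:
            raise ValueError("dG, dH, dS do not close dG = dH - T*dS")


def gibbs_from_kd(params: ThermoParams) -> float:
    """ΔG = −RT ln Kd in kJ/mol."""
    return -R_GAS * params.T * math.log(params.Kd) / 1000.0


def entropy_from_gibbs(dG: float, dH: float, T: float) -> float:
    """ΔS = (ΔH − ΔG)·1000/T in J/(mol·K)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return (dH - dG) * 1000.0 / T


def compute_thermo(params: ThermoParams) -> ThermoResult:
    """Full ΔG/ΔS evaluation for one parameter set."""
    dG = gibbs_from_kd(params)
    dS = entropy_from_gibbs(dG, params.dH, params.T)
    return ThermoResult(dG=dG, dS=dS, dH=params.dH, T=params.T)
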
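#!/usr/bin/env python
"""Thermodynamic parameters of the binding interaction.

Applies dG = -RT ln Kd and the closure dG = dH - T dS with the assumed
Kd = 10 uM, T = 298 K and dH = -30.00 kJ/mol.  The literal relation
yields a positive dG for a micromolar Kd; the convention note in the
output records this sign choice.
"""

import json
from pathlib import Path

from ftirbind.thermo import ThermoParams, compute_thermo

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = ThermoParams(Kd=1.0e-5, T=298.0, dH=-30.00)
    result = compute_thermo(params)
    print(f"Kd = {params.Kd:.1e} M, T = {params.T:.0f} K, "
          f"dH = {params.dH:.2f} kJ/mol")
    print(f"dG = {result.dG:.2f} kJ/mol")
    print(f"dS = {result.dS:.2f} J/(mol·K)")
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "thermodynamics.json").write_text(
        json.dumps(
            {
                "Kd_M": params.Kd,
                "T_K": params.T,
                "dH_kJ_per_mol": params.dH,
                "dG_kJ_per_mol": round(result.dG, 2),
                "dS_J_per_mol_K": round(result.dS, 2),
                "convention_note": result.convention_note,
            },
            indent=2,
        )
    )
    print(f"wrote {OUT / 'thermodynamics.json'}")


if __name__ == "__main__":
    main()
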
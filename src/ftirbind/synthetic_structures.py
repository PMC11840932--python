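"""Synthetic PDB fixtures: an idealized [4Fe4S] cubane and a toy complex.

These are constructed coordinate sets, not crystallographic data: the
cubane places Fe and S on alternating cube corners so that every one of
the 12 Fe-S core bonds has exactly the requested length, and each Fe
carries a cysteine Sγ along the outward body diagonal at the same
length.  The toy protein-DNA complex adds a short strand of DNA
backbone atoms with a known closest contact, for exercising the
distance-selection rules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ideal_cubane_pdb", "toy_complex_pdb"]


def _pdb_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz: np.ndarray,
    element: str,
    hetatm: bool = False,
    occupancy: float = 1.0,
    altloc: str = " ",
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    # columns 13-16: atom name; two-letter elements start at col 13
    if len(element) == 2:
        name_field = f"{name:<4s}"
    else:
        name_field = f" {name:<3s}"
    return (
        f"{record}{serial:5d} {name_field}{altloc}{res_name:>3s} {chain}"
        f"{res_seq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def _cubane_coords(bond_length: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fe, core S and Sγ coordinates of an ideal cubane.

    Fe on four alternating cube corners, S on the other four; the cube
    edge equals the Fe-S bond length, giving 12 equal core bonds.  Each
    Sγ sits ``bond_length`` along the outward body diagonal of its Fe.
    """
    a = bond_length
    fe = np.array([[0, 0, 0], [a, a, 0], [a, 0, a], [0, a, a]], dtype=float)
    s = np.array([[a, 0, 0], [0, a, 0], [0, 0, a], [a, a, a]], dtype=float)
    center = np.full(3, a / 2.0)
    sg = np.empty_like(fe)
    for i, f in enumerate(fe):
        out = f - center
        sg[i] = f + bond_length * out / np.linalg.norm(out)
    return fe, s, sg


def ideal_cubane_pdb(
    bond_length: float = 2.30,
    displace_fe: int | None = None,
    displacement: float = 0.0,
    extra_altloc: bool = False,
) -> str:
    """PDB text for an idealized cubane with cysteine thiolate anchors.

    ``displace_fe``/``displacement`` move one Fe along its bond to the
    first core S (lengthening exactly that bond) for perturbation tests;
    ``extra_altloc`` adds a second, lower-occupancy conformer of FE1 to
    exercise altLoc resolution.
    """
    fe, s, sg = _cubane_coords(bond_length)
    if displace_fe is not None:
        direction = fe[displace_fe] - s[0]
        fe[displace_fe] = fe[displace_fe] + displacement * direction / np.linalg.norm(direction)
    lines = ["HEADER    SYNTHETIC IDEAL CUBANE FIXTURE"]
    serial = 1
    # cysteine Sγ as minimal CYS residues (protein chain A)
    for i, pos in enumerate(sg):
        lines.append(_pdb_line(serial, "SG", "CYS", "A", i + 1, pos, "S"))
        serial += 1
    # cluster heterogroup (SF4) on chain A residue 101
    for i, pos in enumerate(fe):
        altloc = "A" if extra_altloc and i == 0 else " "
        occ = 0.6 if extra_altloc and i == 0 else 1.0
        lines.append(
            _pdb_line(serial, f"FE{i+1}", "SF4", "A", 101, pos, "FE",
                      hetatm=True, occupancy=occ, altloc=altloc)
        )
        serial += 1
        if extra_altloc and i == 0:
            lines.append(
                _pdb_line(serial, "FE1", "SF4", "A", 101, pos + np.array([0.5, 0, 0]),
                          "FE", hetatm=True, occupancy=0.4, altloc="B")
            )
            serial += 1
    for i, pos in enumerate(s):
        lines.append(
            _pdb_line(serial, f"S{i+1}", "SF4", "A", 101, pos, "S", hetatm=True)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_complex_pdb(
    bond_length: float = 2.30,
    n_residues: int = 3,
    n_nucleotides: int = 2,
    closest_contact: float = 3.5,
) -> str:
    """Synthetic protein-DNA complex with a known closest contact.

    A minimal protein chain (ALA backbone N/CA/C/O plus the cubane and
    its cysteines) faces a DNA chain of DA/DT residues carrying backbone
    P, OP1, OP2, O3' and O5' atoms.  The first DNA phosphorus is placed
    exactly ``closest_contact`` Å from the first backbone amide N; all
    other donor-acceptor pairs are farther away.
    """
    fe, s, sg = _cubane_coords(bond_length)
    offset = np.array([-12.0, 0.0, 0.0])
    lines = ["HEADER    SYNTHETIC PROTEIN-DNA TOY FIXTURE"]
    serial = 1
    first_n = None
    for i in range(n_residues):
        base = np.array([0.0, 4.0 * i, 0.0])
        if i == 0:
            first_n = base
        for name, delta, elem in (
            ("N", (0.0, 0.0, 0.0), "N"),
            ("CA", (1.4, 0.4, 0.0), "C"),
            ("C", (2.4, -0.5, 0.0), "C"),
            ("O", (2.4, -1.7, 0.0), "O"),
        ):
            lines.append(
                _pdb_line(serial, name, "ALA", "A", i + 1, base + np.array(delta), elem)
            )
            serial += 1
    for i, pos in enumerate(sg):
        lines.append(
            _pdb_line(serial, "SG", "CYS", "A", n_residues + i + 1, pos + offset, "S")
        )
        serial += 1
    for i, pos in enumerate(fe):
        lines.append(
            _pdb_line(serial, f"FE{i+1}", "SF4", "A", 101, pos + offset, "FE", hetatm=True)
        )
        serial += 1
    for i, pos in enumerate(s):
        lines.append(
            _pdb_line(serial, f"S{i+1}", "SF4", "A", 101, pos + offset, "S", hetatm=True)
        )
        serial += 1
    # DNA chain B: first P exactly closest_contact from the first amide N,
    # along +z so no protein atom comes nearer
    assert first_n is not None
    p0 = first_n + np.array([0.0, 0.0, closest_contact])
    for i in range(n_nucleotides):
        res = "DA" if i % 2 == 0 else "DT"
        base = p0 + np.array([0.0, 5.0 * i, 2.0 * i])
        for name, delta, elem in (
            ("P", (0.0, 0.0, 0.0), "P"),
            ("OP1", (1.2, 0.6, 0.6), "O"),
            ("OP2", (-1.2, 0.6, 0.6), "O"),
            ("O5'", (0.0, 1.2, 1.0), "O"),
            ("O3'", (0.0, -1.2, 1.2), "O"),
        ):
            lines.append(
                _pdb_line(serial, name, res, "B", i + 1, base + np.array(delta), elem)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
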
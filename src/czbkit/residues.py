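"""Amino-acid reference data: side-chain templates, rotamers, radii, charges.

Side chains are described in internal coordinates (Z-matrix rows) so they can
be rebuilt on any backbone from a tuple of chi angles.  Geometry uses standard
Engh–Huber-style bond lengths/angles; ring closure for TRP/HIS/PHE/TYR is
approximate at the 0.01 Å level, which is ample for contact, SASA and
clash-based screening work.

A Z-matrix row is ``(name, a, b, c, bond, angle, torsion)``: the new atom is
bonded to ``c`` at ``bond`` Å, with angle(b, c, new) = ``angle`` degrees and
dihedral(a, b, c, new) = ``torsion``.  ``torsion`` is either a float (fixed,
degrees) or ``("chi", k, offset)`` meaning chi_k + offset.
"""

from __future__ import annotations

from .errors import ConnectivityError

STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

# Ideal backbone internal coordinates (Å / degrees).
BB_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
}

# CB placement off the backbone: dihedral(C, N, CA, CB); sign fixes L-chirality.
CB_ROW = ("CB", "C", "N", "CA", 1.530, 110.4, -122.6)

Chi = tuple[str, int, float]

SIDE_CHAIN_ZMAT: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.524, 110.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.524, 110.7, ("chi", 2, 122.0)),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi", 2, 180.0)),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
        ("CH2", "CD2", "CE3", "CZ3", 1.400, 121.1, 0.0),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", "CG", "CD", "CE", 1.489, 111.5, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", "CA", "CB", "CG", 1.371, 122.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.356, 131.1, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.0, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.0, 180.0),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.492, 104.5, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.503, 105.5, ("chi", 2, 0.0)),
    ],
}

N_CHI: dict[str, int] = {
    "ALA": 0, "GLY": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2,
    "ASP": 2, "ASN": 2, "HIS": 2, "PRO": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

# Coarse backbone-independent rotamer library: (prior weight, chi tuple).
# Weights loosely follow the populations of canonical g-/t/g+ wells.
ROTAMERS: dict[str, list[tuple[float, tuple[float, ...]]]] = {
    "ALA": [(1.0, ())],
    "GLY": [(1.0, ())],
    "PRO": [(1.0, (25.0, -35.0))],
    "SER": [(0.48, (-65.0,)), (0.30, (180.0,)), (0.22, (65.0,))],
    "CYS": [(0.50, (-65.0,)), (0.30, (180.0,)), (0.20, (65.0,))],
    "THR": [(0.45, (-60.0,)), (0.32, (60.0,)), (0.23, (180.0,))],
    "VAL": [(0.60, (175.0,)), (0.25, (-60.0,)), (0.15, (65.0,))],
    "LEU": [(0.55, (-65.0, 175.0)), (0.30, (180.0, 65.0)), (0.15, (-85.0, 65.0))],
    "ILE": [(0.60, (-65.0, 170.0)), (0.20, (-60.0, -60.0)), (0.20, (180.0, 165.0))],
    "MET": [
        (0.30, (-65.0, -65.0, -70.0)),
        (0.25, (-65.0, 180.0, 75.0)),
        (0.25, (180.0, 180.0, 75.0)),
        (0.20, (-65.0, 180.0, 180.0)),
    ],
    "PHE": [(0.50, (-65.0, 90.0)), (0.30, (180.0, 80.0)), (0.20, (65.0, 90.0))],
    "TYR": [(0.50, (-65.0, 90.0)), (0.30, (180.0, 80.0)), (0.20, (65.0, 90.0))],
    "TRP": [(0.40, (-65.0, 95.0)), (0.30, (180.0, -105.0)), (0.30, (-70.0, -90.0))],
    "ASP": [(0.50, (-65.0, -10.0)), (0.30, (180.0, 10.0)), (0.20, (65.0, -15.0))],
    "ASN": [(0.50, (-65.0, -20.0)), (0.30, (180.0, 30.0)), (0.20, (65.0, -20.0))],
    "GLU": [
        (0.40, (-65.0, 180.0, -10.0)),
        (0.30, (180.0, 180.0, 0.0)),
        (0.30, (-65.0, -65.0, -40.0)),
    ],
    "GLN": [
        (0.40, (-65.0, 180.0, -20.0)),
        (0.30, (180.0, 180.0, 0.0)),
        (0.30, (-65.0, -65.0, -40.0)),
    ],
    "LYS": [
        (0.40, (-65.0, 180.0, 180.0, 180.0)),
        (0.30, (180.0, 180.0, 180.0, 180.0)),
        (0.30, (-65.0, -65.0, 180.0, 180.0)),
    ],
    "ARG": [
        (0.35, (-65.0, 180.0, 180.0, 180.0)),
        (0.35, (180.0, 180.0, 180.0, 180.0)),
        (0.30, (-65.0, -65.0, 180.0, 180.0)),
    ],
    "HIS": [(0.50, (-65.0, -75.0)), (0.30, (180.0, 75.0)), (0.20, (65.0, -75.0))],
}


def side_chain_atom_names(res_name: str) -> list[str]:
    """Heavy side-chain atom names (CB outward), template order."""
    if res_name not in SIDE_CHAIN_ZMAT:
        raise KeyError(f"unknown residue type {res_name!r}")
    names = [] if res_name == "GLY" else ["CB"]
    names.extend(row[0] for row in SIDE_CHAIN_ZMAT[res_name])
    return names


def heavy_atom_names(res_name: str) -> list[str]:
    """All heavy atoms of a residue: backbone then side chain."""
    return list(BACKBONE_ATOMS) + side_chain_atom_names(res_name)


# Solvent-accessible-surface radii (Å); probe water 1.4 Å used separately.
SASA_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.10,
}

# Unit-style charges on charged side-chain termini for the surrogate
# electrostic term of the repacking energy.  Histidine treated as a weak
# positive charge split over its ring nitrogens.
PARTIAL_CHARGES: dict[tuple[str, str], float] = {
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25,
}


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a (heavy or hydrogen) PDB atom name."""
    name = atom_name.strip()
    while name and name[0].isdigit():
        name = name[1:]
    if not name:
        raise ValueError(f"unintelligible atom name {atom_name!r}")
    first = name[0].upper()
    if first in ("C", "N", "O", "S", "P", "H"):
        return first
    return first


def parent_heavy_atom(res_name: str, h_name: str) -> str:
    """Heavy atom bonded to hydrogen ``h_name`` in residue ``res_name``.

    Resolution works from the position code of the hydrogen name (HB2 -> B,
    HD11 -> D1, HG21 -> G2) matched against the residue's heavy-atom
    topology.  Raises :class:`ConnectivityError` when no parent exists.
    """
    name = h_name.strip()
    while name and name[0].isdigit():  # old-style "1HB2" spellings
        name = name[1:]
    if not name.startswith("H"):
        raise ConnectivityError(f"{h_name!r} is not a hydrogen atom name")
    if name in ("H", "HN", "HT1", "HT2", "HT3", "H1", "H2", "H3"):
        return "N"
    code = name[1:]
    if code in ("A", "A2", "A3"):
        return "CA"
    heavy = set(heavy_atom_names(res_name)) | {"OXT"}
    candidates = [code]
    if code and code[-1].isdigit():
        candidates.append(code[:-1])
    for cand in candidates:
        for elem in ("C", "N", "O", "S"):
            parent = elem + cand
            if parent in heavy:
                return parent
    raise ConnectivityError(
        f"no parent heavy atom for hydrogen {h_name!r} in residue {res_name}"
    )


def is_aliphatic_hydrogen(res_name: str, h_name: str) -> bool:
    """True when the hydrogen is bonded to a carbon (not N/O/S)."""
    return element_of(parent_heavy_atom(res_name, h_name)) == "C"
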
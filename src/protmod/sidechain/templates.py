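"""Ideal internal-coordinate sidechain templates.

Each amino acid lists its sidechain heavy atoms as Z-matrix rows
``(atom, (a, b, c), bond, angle_deg, torsion)`` where the atom is placed
bonded to ``c`` with the given bond length, angle ``b-c-atom`` and dihedral
``a-b-c-atom``. The torsion is either a fixed value in degrees or
``("chi", k, offset_deg)`` referring to the k-th χ angle (1-based).

Backbone atoms N, CA, C and CB are provided by the caller's frame.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "S": [("N", "CA", "CB", "OG")],
    "C": [("N", "CA", "CB", "SG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "A": [],
}

N_CHI = {aa: len(v) for aa, v in CHI_ATOMS.items()}

_chi = lambda k, off=0.0: ("chi", k, off)

SIDECHAIN_ZMATRIX: Dict[str, List[tuple]] = {
    "A": [],
    "S": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "C": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "T": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "V": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 122.0))],
    "I": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
          ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "L": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0))],
    "D": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
          ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "N": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
          ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "E": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
          ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "Q": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
          ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "M": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
          ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "K": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
          ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "R": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
          ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
          ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
          ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "H": [("CG", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
          ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.356, 131.2, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
          ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "F": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "Y": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
          ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "W": [("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
          ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
          ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
          ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
          ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
          ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "P": [("CG", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.507, 105.5, _chi(2))],
}

SIDECHAIN_ATOMS = {aa: tuple(row[0] for row in rows)
                   for aa, rows in SIDECHAIN_ZMATRIX.items()}
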
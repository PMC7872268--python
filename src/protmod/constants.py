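"""Shared constants: ideal backbone geometry, amino-acid code tables and
per-element parameters for the repulsion / clash terms.

``IdealGeometry`` values can be overridden from a config file (see
:mod:`protmod.config`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AA_ONE = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class IdealGeometry:
    """Idealized backbone covalent geometry (Engh–Huber-style values)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.530
    # angles in radians
    n_ca_c: float = np.deg2rad(111.2)
    ca_c_n: float = np.deg2rad(116.2)
    c_n_ca: float = np.deg2rad(121.7)
    ca_c_o: float = np.deg2rad(120.8)
    n_ca_cb: float = np.deg2rad(110.6)
    omega: float = np.pi


IDEAL = IdealGeometry()

# Hard-sphere radii (Å) for the piecewise-linear repulsion used by the clash
# scorer and the sidechain energy function (SCWRL3-style parameterization).
REPULSION_RADII = {"C": 1.6, "N": 1.3, "O": 1.3, "S": 1.7}

# Lennard-Jones-style sigma (Å) per element for the clashing-sidechain
# counter (residues with an atom closer than factor*sigma_pair).
LJ_SIGMA = {"C": 3.5, "N": 3.3, "O": 3.1, "S": 3.6}

# Penalty ceiling and onset for the repulsion term: zero beyond r_i+r_j,
# linear up to the ceiling which is reached at REPULSION_KNEE*(r_i+r_j).
REPULSION_CEILING = 10.0
REPULSION_KNEE = 0.8254


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a (heavy-atom) PDB atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first not in ("C", "N", "O", "S"):
        raise ValueError(f"unsupported element for atom name {atom_name!r}")
    return first
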
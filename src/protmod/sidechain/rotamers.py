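"""Rotamer construction and χ measurement."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .. import geom
from .templates import CHI_ATOMS, N_CHI, SIDECHAIN_ZMATRIX

__all__ = ["Rotamer", "FlexibleRotamer", "build_rotamer", "measure_chi",
           "get_rotamer_group"]


@dataclass
class Rotamer:
    """A rigid sidechain conformation (includes Cβ)."""

    aa: str
    atom_names: Tuple[str, ...]
    positions: np.ndarray  # (n_atoms, 3)
    self_energy: float = 0.0
    probability: float = 1.0
    res_index: Optional[int] = None
    provenance: Optional[tuple] = None

    def atom(self, name: str) -> np.ndarray:
        return self.positions[self.atom_names.index(name)]


@dataclass
class FlexibleRotamer:
    """An ensemble of sub-rotamers; index 0 is the central one."""

    sub_rotamers: List[Rotamer]
    weights: np.ndarray = field(default=None)
    self_energy: float = 0.0

    def __post_init__(self):
        if not self.sub_rotamers:
            raise ValueError("FlexibleRotamer needs >= 1 sub-rotamer")
        if self.weights is None:
            k = len(self.sub_rotamers)
            self.weights = np.full(k, 1.0 / k)
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()

    @property
    def aa(self) -> str:
        return self.sub_rotamers[0].aa

    @property
    def central(self) -> Rotamer:
        return self.sub_rotamers[0]

    @property
    def probability(self) -> float:
        return self.sub_rotamers[0].probability

    @property
    def res_index(self):
        return self.sub_rotamers[0].res_index


def build_rotamer(aa: str, frame: Dict[str, np.ndarray], chi_deg,
                  res_index: Optional[int] = None,
                  probability: float = 1.0) -> Rotamer:
    """Build a sidechain from ideal internal coordinates.

    ``frame`` must provide N, CA, CB (and C, unused but accepted); ``aa`` is
    a one-letter code. χ angles are in degrees. Glycine has no sidechain and
    raises; alanine returns a Cβ-only rotamer.
    """
    if aa == "G":
        raise ValueError("glycine has no sidechain to build")
    if aa not in SIDECHAIN_ZMATRIX:
        raise ValueError(f"unknown amino acid {aa!r}")
    chi_deg = list(chi_deg)
    if len(chi_deg) != N_CHI[aa]:
        raise ValueError(
            f"{aa} needs {N_CHI[aa]} chi angles, got {len(chi_deg)}")
    coords = {k: np.asarray(v, float) for k, v in frame.items()}
    names = ["CB"]
    for (atom, (a, b, c), bond, angle, tors) in SIDECHAIN_ZMATRIX[aa]:
        if isinstance(tors, tuple):
            _, k, off = tors
            t = np.deg2rad(chi_deg[k - 1] + off)
        else:
            t = np.deg2rad(tors)
        coords[atom] = geom.place_atom(coords[a], coords[b], coords[c],
                                       bond, np.deg2rad(angle), t)
        names.append(atom)
    positions = np.stack([coords[n] for n in names])
    return Rotamer(aa, tuple(names), positions, res_index=res_index,
                   probability=probability)


def measure_chi(aa: str, atoms: Dict[str, np.ndarray]) -> List[float]:
    """Measure χ angles in degrees from an atom-name → position map (must
    include the backbone N, CA and all needed sidechain atoms). Returns NaN
    for angles whose atoms are missing."""
    out = []
    for quad in CHI_ATOMS.get(aa, []):
        if all(q in atoms for q in quad):
            out.append(float(np.degrees(geom.dihedral(
                *(np.asarray(atoms[q], float) for q in quad)))))
        else:
            out.append(float("nan"))
    return out


def get_rotamer_group(lib, aa: str, phi: Optional[float], psi: Optional[float],
                      frame: Dict[str, np.ndarray], mode: str = "RRM",
                      coverage: float = 0.98, k_prob: float = 1.0,
                      res_index: Optional[int] = None):
    """Candidate rotamers for one position.

    Takes the smallest library-entry prefix with cumulative probability ≥
    ``coverage``. In FRM mode each entry is expanded to sub-rotamers at the
    χ means and at ±1σ per χ (capped at 1 + 2·n_chi sub-rotamers). The self
    energy is initialized to ``-k_prob · ln(probability)``; frame terms are
    added by the packing pipeline.
    """
    entries = lib.get(aa, phi, psi)
    if not entries:
        raise ValueError(f"no library entries for {aa}")
    group = []
    cum = 0.0
    nchi = N_CHI[aa]
    for ent_idx, (prob, chis, sigmas) in enumerate(entries):
        chis = list(chis[:nchi])
        base = build_rotamer(aa, frame, chis, res_index, prob)
        base.provenance = (ent_idx, None)
        base.self_energy = -k_prob * np.log(max(prob, 1e-12))
        if mode == "RRM":
            group.append(base)
        elif mode == "FRM":
            subs = [base]
            for ci in range(nchi):
                for sign in (+1.0, -1.0):
                    pert = list(chis)
                    pert[ci] += sign * sigmas[ci]
                    sub = build_rotamer(aa, frame, pert, res_index, prob)
                    sub.provenance = (ent_idx, (ci, sign))
                    sub.self_energy = base.self_energy
                    subs.append(sub)
            flex = FlexibleRotamer(subs)
            flex.self_energy = base.self_energy
            group.append(flex)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        cum += prob
        if cum >= coverage - 1e-9:
            break
    return group
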
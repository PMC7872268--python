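"""Rotamer energy terms.

The default pairwise term is the piecewise-linear hard-sphere repulsion
(zero beyond the radius sum, a ceiling of 10 below 0.8254 of it, linear in
between) evaluated over heavy-atom pairs. Flexible rotamers combine their
sub-rotamer energies thermodynamically via a weighted log-sum-exp.
"""

from __future__ import annotations

from typing import Iterable, Tuple, Union

import numpy as np

from ..constants import REPULSION_RADII, element_of
from ..scoring import clash_penalty
from .rotamers import FlexibleRotamer, Rotamer

__all__ = ["pairwise_energy", "frame_energy", "atoms_repulsion"]

RotamerLike = Union[Rotamer, FlexibleRotamer]

_BACKBONE = {"N", "CA", "C", "O"}


def _radii(names) -> np.ndarray:
    return np.array([REPULSION_RADII[element_of(n)] for n in names])


def atoms_repulsion(names_a, pos_a: np.ndarray, names_b,
                    pos_b: np.ndarray) -> float:
    """Sum of the piecewise-linear repulsion over all inter-set atom pairs."""
    ra = _radii(names_a)
    rb = _radii(names_b)
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    rsum = ra[:, None] + rb[None, :]
    total = 0.0
    for i, j in zip(*np.nonzero(d < rsum)):
        total += clash_penalty(float(d[i, j]), float(rsum[i, j]))
    return total


def _logsumexp_combine(energies: np.ndarray, weights: np.ndarray,
                       beta: float) -> float:
    w = weights / weights.sum()
    x = -beta * energies
    m = x.max()
    return float(-(m + np.log((w * np.exp(x - m)).sum())) / beta)


def pairwise_energy(a: RotamerLike, b: RotamerLike, beta: float = 1.0) -> float:
    """Repulsion between two rotamers; FRM operands are combined over
    sub-rotamer pairs with E = −(1/β)·ln Σ w_k exp(−β E_k)."""
    a_subs = a.sub_rotamers if isinstance(a, FlexibleRotamer) else [a]
    a_w = a.weights if isinstance(a, FlexibleRotamer) else np.array([1.0])
    b_subs = b.sub_rotamers if isinstance(b, FlexibleRotamer) else [b]
    b_w = b.weights if isinstance(b, FlexibleRotamer) else np.array([1.0])
    energies = np.empty((len(a_subs), len(b_subs)))
    for i, ra in enumerate(a_subs):
        for j, rb in enumerate(b_subs):
            energies[i, j] = atoms_repulsion(ra.atom_names, ra.positions,
                                             rb.atom_names, rb.positions)
    if energies.shape == (1, 1):
        return float(energies[0, 0])
    w = np.outer(a_w, b_w).ravel()
    return _logsumexp_combine(energies.ravel(), w, beta)


def frame_energy(r: RotamerLike, frame_atoms: Iterable[Tuple[int, str, np.ndarray]],
                 beta: float = 1.0) -> float:
    """Repulsion of a rotamer against fixed frame atoms.

    ``frame_atoms`` yields ``(residue_index, atom_name, position)``. Atoms of
    the rotamer's own residue and the backbone atoms of its peptide-bonded
    neighbors are excluded.
    """
    subs = r.sub_rotamers if isinstance(r, FlexibleRotamer) else [r]
    weights = r.weights if isinstance(r, FlexibleRotamer) else np.array([1.0])
    ri = r.res_index
    names, coords = [], []
    for (idx, name, pos) in frame_atoms:
        if ri is not None:
            if idx == ri:
                continue
            if abs(idx - ri) == 1 and name in _BACKBONE:
                continue
        names.append(name)
        coords.append(pos)
    if not names:
        return 0.0
    coords = np.asarray(coords, float)
    energies = np.array([atoms_repulsion(s.atom_names, s.positions,
                                         names, coords) for s in subs])
    if len(energies) == 1:
        return float(energies[0])
    return _logsumexp_combine(energies, weights, beta)
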
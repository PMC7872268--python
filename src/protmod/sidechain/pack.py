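"""Sidechain reconstruction pipeline and evaluation metrics.

Pipeline: build rotamer candidates for incomplete residues, fix complete
residues and the backbone as the frame, detect and fix disulfide-bonded
cysteine pairs, compute self/frame/pairwise energies, simplify the graph
(edge decomposition, Goldstein DEE), solve (tree decomposition with A* and
Monte Carlo fallbacks), optionally re-optimize sub-rotamers, and apply the
winning coordinates to the structure.
"""

from __future__ import annotations

import copy
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .. import geom
from ..constants import BACKBONE_ATOMS, LJ_SIGMA, element_of
from ..io_formats import Structure
from ..backbone import reconstruct_cb
from .energy import atoms_repulsion, frame_energy, pairwise_energy
from .library import RotamerLibrary
from .rotamers import (FlexibleRotamer, Rotamer, get_rotamer_group,
                       measure_chi)
from .solvers import (RotamerGraph, dee_goldstein, edge_decompose,
                      solve_astar, solve_monte_carlo, solve_treepack)
from .templates import N_CHI, SIDECHAIN_ATOMS

__all__ = [
    "detect_disulfides", "subrotamer_optimize", "reconstruct_sidechains",
    "chi1_fraction", "count_clashing_sidechains", "rigid_energy",
]

_DISULFIDE_RANGE = (1.8, 2.5)
_DISULFIDE_IDEAL = 2.05


def _central(r):
    return r.central if isinstance(r, FlexibleRotamer) else r


def detect_disulfides(cys_groups: Dict[int, Sequence]) -> List[Tuple[int, int, object, object]]:
    """Greedy disulfide detection.

    ``cys_groups`` maps a position key to its candidate CYS rotamers. A pair
    is a candidate when some rotamer combination puts the Sγ atoms within
    [1.8, 2.5] Å; pairs are selected greedily by closeness to 2.05 Å, each
    cysteine used at most once. Returns ``(i, j, rotamer_i, rotamer_j)``
    tuples with the rigid rotamers realizing the bond.
    """
    keys = sorted(cys_groups)
    candidates = []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ki, kj = keys[a], keys[b]
            best = None
            for ri in cys_groups[ki]:
                for rj in cys_groups[kj]:
                    ci, cj = _central(ri), _central(rj)
                    d = float(np.linalg.norm(ci.atom("SG") - cj.atom("SG")))
                    if _DISULFIDE_RANGE[0] <= d <= _DISULFIDE_RANGE[1]:
                        score = abs(d - _DISULFIDE_IDEAL)
                        if best is None or score < best[0]:
                            best = (score, ri, rj)
            if best is not None:
                candidates.append((best[0], ki, kj, best[1], best[2]))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used = set()
    out = []
    for score, ki, kj, ri, rj in candidates:
        if ki in used or kj in used:
            continue
        used.update((ki, kj))
        out.append((ki, kj, ri, rj))
    return out


def rigid_energy(rotamers: Sequence[Rotamer], frame_atoms=()) -> float:
    """Total rigid energy of a set of placed rotamers: self + frame +
    pairwise repulsion terms."""
    total = 0.0
    for r in rotamers:
        total += r.self_energy
        if frame_atoms:
            total += frame_energy(r, frame_atoms)
    for a in range(len(rotamers)):
        for b in range(a + 1, len(rotamers)):
            total += atoms_repulsion(rotamers[a].atom_names,
                                     rotamers[a].positions,
                                     rotamers[b].atom_names,
                                     rotamers[b].positions)
    return float(total)


def _solve_with_fallbacks(g: RotamerGraph, seed: int = 0):
    try:
        return solve_treepack(g)
    except ValueError:
        pass
    try:
        sols, truncated = solve_astar(g, window=0.0)
        if sols and not truncated:
            return sols[0]
    except MemoryError:
        pass
    return solve_monte_carlo(g, steps=5000, seed=seed)


def subrotamer_optimize(selected: Sequence[FlexibleRotamer],
                        frame_atoms=(), seed: int = 0) -> List[Rotamer]:
    """Expand a solved FRM assignment to rigid sub-rotamers and re-solve.

    The reduced graph contains, per position, the sub-rotamers of the
    selected flexible rotamer with rigid self/frame/pairwise energies. The
    result's rigid energy never exceeds that of the central sub-rotamers
    (the central assignment is part of the search space).
    """
    if not selected:
        return []
    selfs = []
    for flex in selected:
        es = []
        for sub in flex.sub_rotamers:
            e = sub.self_energy
            if frame_atoms:
                e += frame_energy(sub, frame_atoms)
            es.append(e)
        selfs.append(np.array(es))
    edges = {}
    for a in range(len(selected)):
        for b in range(a + 1, len(selected)):
            m = np.zeros((len(selected[a].sub_rotamers),
                          len(selected[b].sub_rotamers)))
            for i, ra in enumerate(selected[a].sub_rotamers):
                for j, rb in enumerate(selected[b].sub_rotamers):
                    m[i, j] = atoms_repulsion(ra.atom_names, ra.positions,
                                              rb.atom_names, rb.positions)
            if np.any(m != 0.0):
                edges[(a, b)] = m
    g = RotamerGraph(selfs, edges)
    assignment, energy = _solve_with_fallbacks(g, seed)
    central_energy = g.energy([0] * len(selected))
    if energy > central_energy + 1e-12:
        assignment = [0] * len(selected)
    return [flex.sub_rotamers[r] for flex, r in zip(selected, assignment)]


# ----------------------------------------------------------------------
# full reconstruction
# ----------------------------------------------------------------------

def _is_complete(residue) -> bool:
    aa = residue.one_letter
    if aa not in SIDECHAIN_ATOMS and aa != "G":
        return True  # unknown residue: leave untouched
    needed = set(BACKBONE_ATOMS)
    if aa != "G":
        needed.add("CB")
        needed.update(SIDECHAIN_ATOMS.get(aa, ()))
    return needed.issubset(residue.atoms)


def reconstruct_sidechains(s: Structure, lib: RotamerLibrary,
                           mode: str = "FRM", coverage: float = 0.98,
                           solver: str = "treepack", eps: float = 0.02,
                           seed: int = 0) -> Structure:
    """Rebuild incomplete sidechains of a structure; returns a new Structure."""
    s = copy.deepcopy(s)
    # global residue indexing with inter-chain padding so that the ±1
    # neighbor exclusion never crosses chains
    gidx = {}
    counter = 0
    for ch in s.chains:
        counter += 10
        for k, r in enumerate(ch.residues):
            gidx[(ch.id, k)] = counter
            counter += 1

    frame_atoms = []
    positions = []  # (chain, res_idx_in_chain, residue)
    for ch in s.chains:
        for k, r in enumerate(ch.residues):
            gi = gidx[(ch.id, k)]
            complete = _is_complete(r)
            aa = r.one_letter
            for name, pos in r.atoms.items():
                if name in BACKBONE_ATOMS or name == "CB" or complete:
                    frame_atoms.append((gi, name, np.asarray(pos, float)))
            if not complete and aa != "G" and aa in SIDECHAIN_ATOMS:
                positions.append((ch, k, r))

    if not positions:
        return s

    groups = []
    for (ch, k, r) in positions:
        aa = r.one_letter
        n_at = np.asarray(r.atoms["N"], float)
        ca = np.asarray(r.atoms["CA"], float)
        c_at = np.asarray(r.atoms["C"], float)
        cb = (np.asarray(r.atoms["CB"], float) if "CB" in r.atoms
              else reconstruct_cb(n_at, ca, c_at))
        frame = {"N": n_at, "CA": ca, "C": c_at, "CB": cb}
        residues = ch.residues
        phi = psi = None
        if k > 0 and "C" in residues[k - 1].atoms:
            phi = geom.dihedral(np.asarray(residues[k - 1].atoms["C"], float),
                                n_at, ca, c_at)
        if k < len(residues) - 1 and "N" in residues[k + 1].atoms:
            psi = geom.dihedral(n_at, ca, c_at,
                                np.asarray(residues[k + 1].atoms["N"], float))
        group = get_rotamer_group(lib, aa, phi, psi, frame, mode=mode,
                                  coverage=coverage,
                                  res_index=gidx[(ch.id, k)])
        groups.append(group)

    # frame term into self energies
    for group in groups:
        for rot in group:
            fe = frame_energy(rot, frame_atoms)
            if isinstance(rot, FlexibleRotamer):
                rot.self_energy += fe
                for sub in rot.sub_rotamers:
                    sub.self_energy += fe
            else:
                rot.self_energy += fe

    # disulfides: fix selected pairs to a single candidate
    cys_positions = {p: groups[p] for p, (ch, k, r) in enumerate(positions)
                     if r.one_letter == "C"}
    for (pi, pj, ri, rj) in detect_disulfides(cys_positions):
        groups[pi] = [ri]
        groups[pj] = [rj]

    selfs = [np.array([r.self_energy for r in group]) for group in groups]
    edges = {}
    for a in range(len(groups)):
        ca_a = np.asarray(positions[a][2].atoms["CA"], float)
        for b in range(a + 1, len(groups)):
            ca_b = np.asarray(positions[b][2].atoms["CA"], float)
            if np.linalg.norm(ca_a - ca_b) > 16.0:
                continue
            m = np.zeros((len(groups[a]), len(groups[b])))
            for i, ra in enumerate(groups[a]):
                for j, rb in enumerate(groups[b]):
                    m[i, j] = pairwise_energy(ra, rb)
            if np.any(m != 0.0):
                edges[(a, b)] = m

    g = RotamerGraph(selfs, edges)
    g, _ = edge_decompose(g, eps)
    g = dee_goldstein(g)
    if solver == "treepack":
        assignment, _ = _solve_with_fallbacks(g, seed)
    elif solver == "astar":
        sols, _ = solve_astar(g, window=0.0)
        assignment = sols[0][0]
    elif solver == "monte_carlo":
        assignment, _ = solve_monte_carlo(g, seed=seed)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    orig = g.to_original(assignment)
    chosen = [groups[p][r] for p, r in enumerate(orig)]

    if mode == "FRM":
        flex = [r for r in chosen if isinstance(r, FlexibleRotamer)]
        if flex:
            flex_idx = [p for p, r in enumerate(chosen)
                        if isinstance(r, FlexibleRotamer)]
            rigid = subrotamer_optimize(flex, frame_atoms, seed)
            for p, rr in zip(flex_idx, rigid):
                chosen[p] = rr
    chosen = [_central(r) for r in chosen]

    for (ch, k, r), rot in zip(positions, chosen):
        keep = {n: p for n, p in r.atoms.items() if n in BACKBONE_ATOMS}
        r.atoms = keep
        for name, pos in zip(rot.atom_names, rot.positions):
            r.atoms[name] = pos.copy()
    return s


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def _chi1(residue) -> Optional[float]:
    aa = residue.one_letter
    if N_CHI.get(aa, 0) < 1:
        return None
    chis = measure_chi(aa, residue.atoms)
    return None if (not chis or np.isnan(chis[0])) else chis[0]


def chi1_fraction(model: Structure, reference: Structure,
                  tol_deg: float = 20.0) -> float:
    """Fraction of residues whose χ1 is within ``tol_deg`` of the reference
    (circular difference); residues lacking χ1 in either are skipped."""
    n_total = 0
    n_ok = 0
    for ch_m, ch_r in zip(model.chains, reference.chains):
        for rm, rr in zip(ch_m.residues, ch_r.residues):
            c_m = _chi1(rm)
            c_r = _chi1(rr)
            if c_m is None or c_r is None:
                continue
            n_total += 1
            diff = abs(np.degrees(geom.wrap_angle(np.deg2rad(c_m - c_r))))
            if diff <= tol_deg + 1e-9:
                n_ok += 1
    return n_ok / n_total if n_total else 1.0


def count_clashing_sidechains(s: Structure, factor: float = 0.6,
                              sigma_table: Optional[Dict[str, float]] = None) -> int:
    """Number of residues with a sidechain atom closer than
    ``factor * σ_pair`` to any atom of a different residue (σ_pair = mean of
    the two atoms' per-element σ). Backbone contacts of peptide-bonded
    neighbors are excluded."""
    sigma = sigma_table or LJ_SIGMA
    atoms = []  # (chain_idx, res_idx, name, sigma, pos, is_sidechain)
    for ci, ch in enumerate(s.chains):
        for ri, r in enumerate(ch.residues):
            for name, pos in r.atoms.items():
                el = element_of(name)
                if el not in sigma:
                    raise KeyError(f"element {el} missing from sigma table")
                atoms.append((ci, ri, name, sigma[el],
                              np.asarray(pos, float),
                              name not in BACKBONE_ATOMS))
    clashing = set()
    for a in range(len(atoms)):
        ci_a, ri_a, name_a, s_a, p_a, side_a = atoms[a]
        for b in range(a + 1, len(atoms)):
            ci_b, ri_b, name_b, s_b, p_b, side_b = atoms[b]
            if ci_a == ci_b and ri_a == ri_b:
                continue
            if not (side_a or side_b):
                continue
            if (ci_a == ci_b and abs(ri_a - ri_b) == 1
                    and not (side_a and side_b)):
                continue  # peptide-bonded neighbor backbone contact
            thresh = factor * 0.5 * (s_a + s_b)
            if np.linalg.norm(p_a - p_b) < thresh:
                if side_a:
                    clashing.add((ci_a, ri_a))
                if side_b:
                    clashing.add((ci_b, ri_b))
    return len(clashing)
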
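"""Deterministic synthetic fixtures.

Everything needed by the test-suite — helices, hairpins, toy proteins with
packed sidechains, loop-modelling cases, decoy sets and miniature fragment
databases — is generated programmatically from seeds; no downloads.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .backbone import BackboneList, backbone_from_torsions, ca_rmsd, ccd_close
from .constants import ONE_TO_THREE
from .fragdb import FragDB, StructureDB
from .io_formats import Chain, Residue, Structure
from .modelling import Gap, ModellingHandle
from .sidechain import (RotamerLibrary, build_rotamer,
                        count_clashing_sidechains, N_CHI)

__all__ = [
    "make_ideal_helix", "make_strand", "make_hairpin", "make_toy_protein",
    "structure_from_backbone", "make_loop_case", "make_decoy_set",
    "make_mini_db", "helix_loop_helix",
]

_HELIX = (np.deg2rad(-57.0), np.deg2rad(-47.0))
_STRAND = (np.deg2rad(-120.0), np.deg2rad(130.0))


def make_ideal_helix(n: int, seed: int = 0, sequence: Optional[str] = None
                     ) -> BackboneList:
    """Ideal α-helix (φ = −57°, ψ = −47°)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = sequence or "A" * n
    return backbone_from_torsions(seq, [_HELIX[0]] * n, [_HELIX[1]] * n)


def make_strand(n: int, seed: int = 0, sequence: Optional[str] = None
                ) -> BackboneList:
    """Extended β-strand (φ = −120°, ψ = 130°)."""
    seq = sequence or "A" * n
    return backbone_from_torsions(seq, [_STRAND[0]] * n, [_STRAND[1]] * n)


def make_hairpin(n_strand: int = 5, seed: int = 0) -> BackboneList:
    """Two antiparallel strands joined by a type-I' style turn."""
    n = 2 * n_strand + 2
    phi = []
    psi = []
    for _ in range(n_strand):
        phi.append(_STRAND[0]); psi.append(_STRAND[1])
    # turn
    phi.append(np.deg2rad(55.0)); psi.append(np.deg2rad(40.0))
    phi.append(np.deg2rad(80.0)); psi.append(np.deg2rad(5.0))
    for _ in range(n_strand):
        phi.append(_STRAND[0]); psi.append(_STRAND[1])
    return backbone_from_torsions("A" * n, phi, psi)


def helix_loop_helix(n_res: int, seed: int = 0,
                     sequence: Optional[str] = None,
                     loop_tors: Optional[Sequence[Tuple[float, float]]] = None
                     ) -> BackboneList:
    """Helix–loop–helix backbone with a 4-residue coil linker."""
    if n_res < 12:
        raise ValueError("need at least 12 residues")
    rng = np.random.default_rng(seed)
    n_loop = 4
    n_h1 = (n_res - n_loop) // 2
    n_h2 = n_res - n_loop - n_h1
    loop_tors = list(loop_tors) if loop_tors is not None else [
        (-70.0, 140.0), (-100.0, 120.0), (-85.0, -10.0), (-130.0, 70.0)]
    phi, psi = [], []
    for _ in range(n_h1):
        phi.append(_HELIX[0]); psi.append(_HELIX[1])
    for k in range(n_loop):
        p, q = loop_tors[k % len(loop_tors)]
        jitter = rng.normal(0.0, 3.0, 2)
        phi.append(np.deg2rad(p + jitter[0]))
        psi.append(np.deg2rad(q + jitter[1]))
    for _ in range(n_h2):
        phi.append(_HELIX[0]); psi.append(_HELIX[1])
    seq = sequence or _random_sequence(n_res, rng)
    return backbone_from_torsions(seq, phi, psi)


def _random_sequence(n: int, rng) -> str:
    pool = "STVLIDNEQMA"
    return "".join(pool[int(k)] for k in rng.integers(0, len(pool), n))


def structure_from_backbone(bb: BackboneList, chain_id: str = "A",
                            start_number: int = 1) -> Structure:
    """Materialize a BackboneList as a Structure (N, CA, C, O, CB)."""
    chain = Chain(chain_id)
    for i in range(len(bb)):
        aa = bb.sequence[i]
        res = Residue(start_number + i, "", ONE_TO_THREE.get(aa, "UNK"))
        res.atoms["N"] = bb.n[i].copy()
        res.atoms["CA"] = bb.ca[i].copy()
        res.atoms["C"] = bb.c[i].copy()
        res.atoms["O"] = bb.o[i].copy()
        if not np.isnan(bb.cb[i]).any():
            res.atoms["CB"] = bb.cb[i].copy()
        chain.residues.append(res)
    return Structure([chain])


def make_toy_protein(n_res: int, seed: int = 0,
                     lib: Optional[RotamerLibrary] = None,
                     max_attempts: int = 200) -> Structure:
    """Helix–loop–helix toy protein with clash-free packed sidechains.

    Sidechains are greedily chosen from the library (probability order with
    seeded jitter) rejecting rotamers that violate the 0.6σ clash criterion;
    raises if the rejection cap is exceeded.
    """
    if lib is None:
        from .sidechain import load_mini_library
        lib = load_mini_library()
    rng = np.random.default_rng(seed)
    bb = helix_loop_helix(n_res, seed)
    s = structure_from_backbone(bb)
    residues = s.chains[0].residues
    for i, res in enumerate(residues):
        aa = res.one_letter
        if N_CHI.get(aa, 0) == 0:
            continue
        frame = {"N": bb.n[i], "CA": bb.ca[i], "C": bb.c[i], "CB": bb.cb[i]}
        entries = lib.get(aa, None, None)
        if not entries:
            continue
        order = np.argsort([-p + rng.normal(0, 0.05) for p, _, _ in entries])
        placed = False
        attempts = 0
        for k in order:
            prob, chis, sigmas = entries[int(k)]
            for jitter in (0.0, 5.0, -5.0, 10.0, -10.0):
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        f"sidechain rejection cap exceeded at residue {i}")
                trial = [c + jitter for c in chis[:N_CHI[aa]]]
                rot = build_rotamer(aa, frame, trial)
                for name, pos in zip(rot.atom_names, rot.positions):
                    res.atoms[name] = pos.copy()
                if _residue_clash_free(s, i):
                    placed = True
                    break
            if placed:
                break
        if not placed:
            # fall back to bare CB
            for name in list(res.atoms):
                if name not in ("N", "CA", "C", "O", "CB"):
                    del res.atoms[name]
    if count_clashing_sidechains(s) != 0:
        raise RuntimeError("toy protein still has clashing sidechains")
    return s


def _residue_clash_free(s: Structure, res_idx: int) -> bool:
    """0.6σ clash check of one residue's sidechain vs all placed atoms."""
    from .constants import LJ_SIGMA, element_of
    residues = s.chains[0].residues
    target = residues[res_idx]
    for name, pos in target.atoms.items():
        if name in ("N", "CA", "C", "O"):
            continue
        sa = LJ_SIGMA[element_of(name)]
        for j, other in enumerate(residues):
            if j == res_idx:
                continue
            backbone_neighbor = abs(j - res_idx) == 1
            for oname, opos in other.atoms.items():
                if backbone_neighbor and oname in ("N", "CA", "C", "O"):
                    continue
                sb = LJ_SIGMA[element_of(oname)]
                if np.linalg.norm(np.asarray(pos) - np.asarray(opos)) \
                        < 0.6 * 0.5 * (sa + sb):
                    return False
    return True


def make_loop_case(s: Structure, span: Tuple[int, int],
                   chain_id: str = "A"):
    """Remove the backbone of ``span`` (0-based, end-exclusive) from a
    structure, returning ``(ModellingHandle, reference_loop)`` where the
    reference includes one stem residue on each side."""
    from .backbone import backbone_from_chain
    chain = s.chain(chain_id)
    start, end = span
    if start < 1 or end > len(chain.residues) - 1:
        raise ValueError("span must be interior (one stem on each side)")
    bb = backbone_from_chain(s, chain_id)
    mh = ModellingHandle(bb.sequence, chain_id)
    mh.set_backbone(bb, 0)
    reference = bb.extract(start - 1, end + 1)
    for arr in (mh.n, mh.ca, mh.c, mh.o, mh.cb):
        arr[start:end] = np.nan
    mh.present[start:end] = False
    mh.sidechains = {k: v for k, v in mh.sidechains.items()
                     if not (start <= k < end)}
    mh.gaps = [Gap(start - 1, end, bb.sequence[start:end])]
    return mh, reference


def make_decoy_set(reference: BackboneList, n: int, seed: int = 0,
                   sigma_ladder: Sequence[float] = (2.0, 5.0, 10.0, 20.0)
                   ) -> List[Tuple[BackboneList, float]]:
    """Torsion-perturbed, CCD-re-closed decoys of a reference loop with
    Cα-RMSD labels (sigma ladder in degrees)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_anchor = reference.stem_atoms(0)
    c_anchor = reference.stem_atoms(len(reference) - 1)
    out = []
    for k in range(n):
        sigma = np.deg2rad(sigma_ladder[k % len(sigma_ladder)])
        decoy = reference.copy()
        if sigma > 0:
            for i in range(1, len(decoy) - 1):
                decoy.set_torsion(i, "phi", decoy.phi[i] + rng.normal(0, sigma))
                decoy.set_torsion(i, "psi", decoy.psi[i] + rng.normal(0, sigma))
            decoy, _, _ = ccd_close(decoy, n_anchor, c_anchor)
        out.append((decoy, ca_rmsd(decoy, reference)))
    return out


def make_mini_db(structures: Iterable, lengths: Iterable[int] = range(3, 15),
                 rmsd_thresh: float = 1.0) -> Tuple[StructureDB, FragDB]:
    """Build a StructureDB + FragDB from BackboneLists or Structures."""
    from .backbone import backbone_from_chain
    sdb = StructureDB()
    count = 0
    for item in structures:
        if isinstance(item, BackboneList):
            bb = item
        else:
            bb = backbone_from_chain(item, item.chains[0].id)
        sdb.add_chain(f"fx{count:03d}", "A", bb, bb.sequence)
        count += 1
    if count == 0:
        raise ValueError("need at least one structure")
    fdb = FragDB(1.0, 20.0)
    for length in lengths:
        fdb.add_fragments(length, rmsd_thresh, sdb)
    return sdb, fdb
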
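"""End-to-end comparative modelling pipeline.

``build_raw_model`` transfers conserved coordinates from an aligned template
into a :class:`ModellingHandle` (partial model + ordered gap list). Gaps are
then resolved by deletion relaxation, database-driven loop filling and a
Monte-Carlo fallback; sidechains are rebuilt and the model is regularized.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import geom
from .backbone import (BackboneList, backbone_from_chain,
                       backbone_from_torsions, ccd_close, reconstruct_cb)
from .constants import IDEAL, ONE_TO_THREE
from .fragdb import FragDB, FragmentAddress, StructureDB, assign_ss, stem_geometry
from .io_formats import Alignment, Chain, Residue, Structure
from .scoring import ScoringEnvironment, combine, score_segment
from .sidechain import reconstruct_sidechains

__all__ = [
    "Gap", "ModellingHandle", "PipelineConfig", "ModellingError",
    "build_raw_model", "handle_deletions", "extend_gap",
    "fill_loops_by_database", "fill_loops_monte_carlo", "regularize",
    "build_from_raw_model",
]

_SCORE_KINDS = ("cbeta", "cb_packing", "clash", "hbond", "torsion", "reduced")


class ModellingError(RuntimeError):
    pass


@dataclass
class Gap:
    """A stretch of target residues without coordinates.

    ``before``/``after`` are target indices of the bounding modelled
    residues (−1 / L for chain termini); ``target_seq`` is the sequence to
    be built (empty for a pure deletion).
    """

    before: int
    after: int
    target_seq: str

    @property
    def is_deletion(self) -> bool:
        return not self.target_seq

    @property
    def length(self) -> int:
        return len(self.target_seq)


@dataclass
class PipelineConfig:
    max_loop_length: int = 12
    candidates_per_gap: int = 20
    max_extra_bins: int = 2
    ccd_tol: float = 0.1
    ccd_max_iter: int = 200
    score_weights: Dict[str, float] = field(default_factory=lambda: {
        "cbeta": 1.0, "cb_packing": 1.0, "clash": 1.0, "hbond": 1.0,
        "torsion": 1.0, "reduced": 1.0, "stem_rmsd": 1.0})
    mc_sweeps: int = 50
    mc_t0: float = 100.0
    mc_cool: float = 0.92
    mc_ccd_iter: int = 30
    max_terminal_overhang: int = 10
    regularizer_iterations: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


class ModellingHandle:
    """Partial single-chain model plus its ordered gap list."""

    def __init__(self, target_seq: str, chain_id: str = "A"):
        L = len(target_seq)
        self.target_seq = target_seq
        self.chain_id = chain_id
        self.n = np.full((L, 3), np.nan)
        self.ca = np.full((L, 3), np.nan)
        self.c = np.full((L, 3), np.nan)
        self.o = np.full((L, 3), np.nan)
        self.cb = np.full((L, 3), np.nan)
        self.present = np.zeros(L, dtype=bool)
        self.ss = ["C"] * L  # template-derived secondary structure
        self.sidechains: Dict[int, Dict[str, np.ndarray]] = {}
        self.gaps: List[Gap] = []

    def __len__(self):
        return len(self.target_seq)

    def copy(self) -> "ModellingHandle":
        return copy.deepcopy(self)

    def backbone_view(self, start: int, end: int) -> BackboneList:
        if not self.present[start:end].all():
            raise ValueError("absent residues in range")
        return BackboneList(self.target_seq[start:end], self.n[start:end],
                            self.ca[start:end], self.c[start:end],
                            self.o[start:end], self.cb[start:end])

    def set_backbone(self, bb: BackboneList, start: int,
                     rename: bool = True) -> None:
        """Write loop coordinates at [start, start+len); the handle's target
        sequence stays authoritative (fragment Cβ is re-derived when the
        fragment and target disagree on glycine)."""
        end = start + len(bb)
        self.n[start:end] = bb.n
        self.ca[start:end] = bb.ca
        self.c[start:end] = bb.c
        self.o[start:end] = bb.o
        for k in range(len(bb)):
            i = start + k
            if self.target_seq[i] == "G":
                self.cb[i] = np.nan
            elif np.isnan(bb.cb[k]).any():
                self.cb[i] = reconstruct_cb(bb.n[k], bb.ca[k], bb.c[k])
            else:
                self.cb[i] = bb.cb[k]
            self.sidechains.pop(i, None)
        self.present[start:end] = True

    def environment(self) -> ScoringEnvironment:
        env = ScoringEnvironment(self.target_seq)
        for start, end in self._present_runs():
            env.set_range(self.backbone_view(start, end), start)
        return env

    def _present_runs(self):
        runs = []
        i = 0
        L = len(self)
        while i < L:
            if self.present[i]:
                j = i
                while j < L and self.present[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        return runs

    def stem(self, i: int) -> np.ndarray:
        return np.stack([self.n[i], self.ca[i], self.c[i]])

    def to_structure(self) -> Structure:
        """Materialize the modelled residues as a Structure (1-based author
        numbering following target indices)."""
        chain = Chain(self.chain_id)
        for i in range(len(self)):
            if not self.present[i]:
                continue
            aa = self.target_seq[i]
            res = Residue(i + 1, "", ONE_TO_THREE.get(aa, "UNK"))
            res.atoms["N"] = self.n[i].copy()
            res.atoms["CA"] = self.ca[i].copy()
            res.atoms["C"] = self.c[i].copy()
            res.atoms["O"] = self.o[i].copy()
            if not np.isnan(self.cb[i]).any():
                res.atoms["CB"] = self.cb[i].copy()
            for name, pos in self.sidechains.get(i, {}).items():
                res.atoms[name] = np.asarray(pos, float).copy()
            chain.residues.append(res)
        return Structure([chain])


# ----------------------------------------------------------------------
# raw model
# ----------------------------------------------------------------------

def build_raw_model(aln: Alignment, template_row: int = 1,
                    chain_id: str = "A") -> ModellingHandle:
    """Transfer aligned template coordinates onto the target sequence."""
    if template_row not in aln.attachments:
        raise ValueError(f"alignment row {template_row} has no attached view")
    structure, tpl_chain_id, colmap = aln.attachments[template_row]
    tpl_residues = structure.chain(tpl_chain_id).residues
    target = aln.ungapped(0)
    mh = ModellingHandle(target, chain_id)

    try:
        tpl_bb = backbone_from_chain(structure, tpl_chain_id)
        tpl_ss = assign_ss(tpl_bb)
    except ValueError:
        tpl_ss = "C" * len(tpl_residues)

    ti = 0
    deletion_boundaries = set()
    pending_deletion = False
    for col in range(len(aln)):
        t_char = aln.rows[0][col]
        p_char = aln.rows[template_row][col]
        if t_char != "-" and p_char != "-":
            res = tpl_residues[colmap[col]]
            if pending_deletion and ti > 0:
                deletion_boundaries.add(ti)
            pending_deletion = False
            mh.n[ti] = res.atoms["N"]
            mh.ca[ti] = res.atoms["CA"]
            mh.c[ti] = res.atoms["C"]
            mh.o[ti] = res.atoms["O"]
            mh.ss[ti] = tpl_ss[colmap[col]]
            if target[ti] != "G":
                if "CB" in res.atoms:
                    mh.cb[ti] = res.atoms["CB"]
                else:
                    mh.cb[ti] = reconstruct_cb(mh.n[ti], mh.ca[ti], mh.c[ti])
            if t_char == p_char:
                side = {k: np.asarray(v, float) for k, v in res.atoms.items()
                        if k not in ("N", "CA", "C", "O", "CB")}
                if side:
                    mh.sidechains[ti] = side
            mh.present[ti] = True
            ti += 1
        elif t_char != "-":
            pending_deletion = False
            ti += 1
        else:  # template-only column: deletion
            if mh.present[:ti].any():
                pending_deletion = True

    # gap list: absent runs, then zero-length deletion boundaries
    L = len(mh)
    gaps = []
    i = 0
    while i < L:
        if not mh.present[i]:
            j = i
            while j < L and not mh.present[j]:
                j += 1
            before = i - 1
            after = j
            gaps.append(Gap(before if i > 0 else -1, after if j < L else L,
                            target[i:j]))
            i = j
        else:
            i += 1
    for b in sorted(deletion_boundaries):
        if mh.present[b - 1] and mh.present[b]:
            gaps.append(Gap(b - 1, b, ""))
    gaps.sort(key=lambda g: (g.before, g.after))
    mh.gaps = gaps
    return mh


# ----------------------------------------------------------------------
# gap machinery
# ----------------------------------------------------------------------

def _bonds_ok(bb: BackboneList) -> bool:
    for i in range(len(bb) - 1):
        d = np.linalg.norm(bb.n[i + 1] - bb.c[i])
        if not (1.2 <= d <= 1.5):
            return False
    return True


def _segment_scores(env: ScoringEnvironment, start: int, end: int,
                    tables) -> Dict[str, float]:
    table_for = {"cbeta": tables.get("cbeta"), "reduced": tables.get("reduced"),
                 "torsion": tables.get("torsion"),
                 "cb_packing": tables.get("packing"),
                 "clash": None, "hbond": None}
    out = {}
    for kind in _SCORE_KINDS:
        if kind in ("cbeta", "reduced", "torsion", "cb_packing") \
                and table_for[kind] is None:
            out[kind] = 0.0
            continue
        out[kind] = score_segment(env, start, end, kind, table_for[kind])
    return out


def handle_deletions(mh: ModellingHandle, cfg: PipelineConfig,
                     flank: int = 2) -> ModellingHandle:
    """Resolve pure deletions by relaxing up to ``flank`` residues on each
    side with CCD; accepted when the re-bridged segment is clash-free and
    all peptide bonds are within [1.2, 1.5] Å."""
    remaining = []
    for gap in mh.gaps:
        if not gap.is_deletion or gap.before < 0 or gap.after >= len(mh):
            remaining.append(gap)
            continue
        n_stem = gap.before - flank
        c_stem = gap.after + flank
        if (n_stem < 0 or c_stem >= len(mh)
                or not mh.present[n_stem:c_stem + 1].all()):
            remaining.append(gap)
            continue
        seq = mh.target_seq[n_stem:c_stem + 1]
        Ll = len(seq)
        rng = np.random.default_rng(cfg.seed)
        starts = [([p] * Ll, [q] * Ll) for (p, q) in
                  [(-120.0, 120.0), (-80.0, -20.0), (-100.0, 120.0),
                   (-70.0, 140.0), (-57.0, -47.0), (-140.0, 150.0)]]
        starts += [(rng.uniform(-150, -50, Ll), rng.uniform(-60, 160, Ll))
                   for _ in range(30)]
        accepted = None
        for (p, q) in starts:
            loop0 = backbone_from_torsions(seq, np.deg2rad(p), np.deg2rad(q))
            closed, converged, _ = ccd_close(loop0, mh.stem(n_stem),
                                             mh.stem(c_stem),
                                             max_iter=cfg.ccd_max_iter,
                                             tol=cfg.ccd_tol)
            if not converged or not _bonds_ok(closed):
                continue
            env = mh.environment()
            env.set_range(closed.extract(1, Ll - 1), n_stem + 1)
            if score_segment(env, n_stem + 1, c_stem, "clash") == 0.0:
                accepted = closed
                break
        if accepted is not None:
            mh.set_backbone(accepted.extract(1, Ll - 1), n_stem + 1)
        else:
            remaining.append(gap)
    mh.gaps = remaining
    return mh


def extend_gap(gap: Gap, mh: ModellingHandle, max_length: int) -> List[Gap]:
    """Ordered candidate gap extents.

    Enumerates conversions of flanking modelled residues into loop, ordered
    by total modelled length, then by how few non-coil ('H'/'E') template
    residues are consumed, then N-side first. Both stems must remain
    modelled residues.
    """
    L = len(mh)
    base_len = gap.after - gap.before - 1
    out = []
    for n_ext in range(0, gap.before + 1):
        if not mh.present[gap.before - n_ext:gap.before + 1].all():
            break
        for c_ext in range(0, L - gap.after):
            if not mh.present[gap.after:gap.after + c_ext + 1].all():
                break
            total = base_len + n_ext + c_ext
            if total > max_length:
                break
            new_before = gap.before - n_ext
            new_after = gap.after + c_ext
            if new_before < 0 or new_after >= L:
                continue
            noncoil = sum(1 for i in range(new_before + 1, gap.before + 1)
                          if mh.ss[i] != "C")
            noncoil += sum(1 for i in range(gap.after, new_after)
                           if mh.ss[i] != "C")
            out.append((total, noncoil, -n_ext,
                        Gap(new_before, new_after,
                            mh.target_seq[new_before + 1:new_after])))
    out.sort(key=lambda t: t[:3])
    return [t[3] for t in out]


def fill_loops_by_database(mh: ModellingHandle, fdb: FragDB, sdb: StructureDB,
                           tables: dict, cfg: PipelineConfig,
                           weights: Optional[Dict[str, float]] = None
                           ) -> ModellingHandle:
    """Fill gaps with stem-geometry-matched database fragments.

    Per gap, extents from :func:`extend_gap` are tried in order; candidates
    are fitted with CCD, scored with the backbone scorer set plus the
    pre-CCD stem RMSD, and the best combined score is committed.
    """
    weights = weights or cfg.score_weights
    env = mh.environment()
    remaining = []
    for gap in mh.gaps:
        if gap.before < 0 or gap.after >= len(mh):
            remaining.append(gap)  # terminal gaps go to the MC stage
            continue
        committed = False
        for extent in extend_gap(gap, mh, cfg.max_loop_length):
            l = extent.after - extent.before - 1
            if l < 1:
                continue
            try:
                g = stem_geometry(mh.stem(extent.before),
                                  mh.stem(extent.after), l)
            except ValueError:
                continue
            addrs: List[FragmentAddress] = []
            for extra in range(cfg.max_extra_bins + 1):
                addrs = fdb.query(g, extra)
                if len(addrs) >= cfg.candidates_per_gap:
                    break
            addrs = addrs[:cfg.candidates_per_gap]
            if not addrs:
                continue
            best = None
            for addr in addrs:
                if addr.offset < 1 or (addr.offset + addr.length + 1
                                       > sdb.chain_length(addr.chain_index)):
                    continue
                span, _, _ = sdb.get_fragment(FragmentAddress(
                    addr.chain_index, addr.offset - 1, addr.length + 2))
                # pre-CCD stem RMSD: superpose candidate on both stems
                P = np.concatenate([span.stem_atoms(0),
                                    span.stem_atoms(len(span) - 1)])
                Q = np.concatenate([mh.stem(extent.before),
                                    mh.stem(extent.after)])
                R, t, stem_rmsd = geom.kabsch(P, Q)
                closed, converged, _ = ccd_close(
                    span, mh.stem(extent.before), mh.stem(extent.after),
                    max_iter=cfg.ccd_max_iter, tol=cfg.ccd_tol)
                if not converged or not _bonds_ok(closed):
                    continue
                inner = closed.extract(1, len(closed) - 1)
                env.set_range(inner, extent.before + 1)
                try:
                    scores = _segment_scores(env, extent.before + 1,
                                             extent.after, tables)
                finally:
                    env.clear_range(extent.before + 1, extent.after)
                    for (rs, re) in mh._present_runs():
                        s0 = max(rs, extent.before + 1)
                        e0 = min(re, extent.after)
                        if s0 < e0:
                            env.set_range(mh.backbone_view(s0, e0), s0)
                scores["stem_rmsd"] = stem_rmsd
                total = combine(scores, weights)
                if best is None or total < best[0]:
                    best = (total, inner, extent)
            if best is not None:
                _, inner, extent = best
                mh.set_backbone(inner, extent.before + 1)
                env.set_range(inner, extent.before + 1)
                committed = True
                break
        if not committed:
            remaining.append(gap)
    mh.gaps = remaining
    return mh


def fill_loops_monte_carlo(mh: ModellingHandle, torsion_tables,
                           tables: dict, cfg: PipelineConfig,
                           seed: Optional[int] = None,
                           weights: Optional[Dict[str, float]] = None
                           ) -> ModellingHandle:
    """Simulated-annealing fallback for remaining gaps.

    Loops are initialized from per-amino-acid φ/ψ distributions, closed with
    CCD, and refined by Metropolis-resampling single-residue torsions; the
    best stereochemically valid state is committed. Gap elongation (without
    the database length cap) is applied on persistent failure.
    """
    weights = weights or cfg.score_weights
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    remaining = []
    for gap in mh.gaps:
        if gap.before < 0 or gap.after >= len(mh):
            if _fill_terminal(mh, gap, torsion_tables, cfg, rng):
                continue
            remaining.append(gap)
            continue
        extents = [gap] + extend_gap(gap, mh, max_length=len(mh))
        solved = False
        for extent in extents[:4]:
            if extent.before < 0 or extent.after >= len(mh):
                continue
            if _mc_close_gap(mh, extent, torsion_tables, tables, cfg,
                             weights, rng):
                solved = True
                break
        if not solved:
            remaining.append(gap)
    mh.gaps = remaining
    return mh


def _sample_torsions(seq: str, torsion_tables, rng):
    phi = np.empty(len(seq))
    psi = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if torsion_tables is not None:
            phi[i], psi[i] = torsion_tables.sample(aa, rng)
        else:
            phi[i] = rng.uniform(-np.pi, 0.0)
            psi[i] = rng.uniform(-np.pi, np.pi)
    return phi, psi


def _mc_close_gap(mh, extent: Gap, torsion_tables, tables, cfg, weights,
                  rng) -> bool:
    seq = mh.target_seq[extent.before:extent.after + 1]
    Ll = len(seq)
    if Ll < 3:
        return False
    n_anchor = mh.stem(extent.before)
    c_anchor = mh.stem(extent.after)
    env = mh.environment()

    def evaluate(loop):
        inner = loop.extract(1, Ll - 1)
        env.set_range(inner, extent.before + 1)
        try:
            scores = _segment_scores(env, extent.before + 1, extent.after,
                                     tables)
        finally:
            env.clear_range(extent.before + 1, extent.after)
        scores["stem_rmsd"] = 0.0
        return combine(scores, weights), scores["clash"]

    phi, psi = _sample_torsions(seq, torsion_tables, rng)
    loop = backbone_from_torsions(seq, phi, psi)
    loop, conv, arms = ccd_close(loop, n_anchor, c_anchor,
                                 max_iter=cfg.ccd_max_iter, tol=cfg.ccd_tol)
    score, clash = evaluate(loop)
    cur = (loop, conv, arms, score, clash)
    best = cur if conv and clash == 0.0 and _bonds_ok(loop) else None
    temp = cfg.mc_t0
    steps = cfg.mc_sweeps * max(Ll - 2, 1)
    penalty_w = 10.0
    cur_obj = score + penalty_w * arms
    for step in range(steps):
        i = 1 + int(rng.integers(Ll - 2))
        trial = cur[0].copy()
        if torsion_tables is not None:
            nphi, npsi = torsion_tables.sample(seq[i], rng)
        else:
            nphi = rng.uniform(-np.pi, 0.0)
            npsi = rng.uniform(-np.pi, np.pi)
        trial.set_torsion(i, "phi", nphi)
        if i < Ll - 1:
            trial.set_torsion(i, "psi", npsi)
        trial, conv, arms = ccd_close(trial, n_anchor, c_anchor,
                                      max_iter=cfg.mc_ccd_iter,
                                      tol=cfg.ccd_tol)
        score, clash = evaluate(trial)
        obj = score + penalty_w * arms
        accept = obj <= cur_obj or rng.random() < np.exp(
            -(obj - cur_obj) / max(temp, 1e-9))
        if accept:
            cur = (trial, conv, arms, score, clash)
            cur_obj = obj
            if conv and clash == 0.0 and _bonds_ok(trial):
                if best is None or score < best[3]:
                    best = cur
        if (step + 1) % max(Ll - 2, 1) == 0:
            temp *= cfg.mc_cool
    if best is None:
        return False
    mh.set_backbone(best[0].extract(1, Ll - 1), extent.before + 1)
    return True


def _fill_terminal(mh, gap: Gap, torsion_tables, cfg, rng) -> bool:
    """Extend an unmodelled terminus by sampled torsions (short overhangs
    only; longer ones are trimmed later with a warning)."""
    L = len(mh)
    length = gap.length
    if length == 0:
        return True
    if length > cfg.max_terminal_overhang:
        warnings.warn(
            f"terminal overhang of {length} residues trimmed")
        return False
    if gap.before < 0:  # N-terminal: build backwards from the anchor
        anchor = gap.after
        seq = mh.target_seq[:anchor + 1]
        phi, psi = _sample_torsions(seq, torsion_tables, rng)
        bb = backbone_from_torsions(seq, phi, psi)
        # superpose the built segment's last residue onto the anchor residue
        R, t, _ = geom.kabsch(bb.stem_atoms(len(bb) - 1), mh.stem(anchor))
        bb.transform(R, t)
        mh.set_backbone(bb.extract(0, len(bb) - 1), 0)
    else:  # C-terminal
        anchor = gap.before
        seq = mh.target_seq[anchor:]
        phi, psi = _sample_torsions(seq, torsion_tables, rng)
        bb = backbone_from_torsions(seq, phi, psi)
        R, t, _ = geom.kabsch(bb.stem_atoms(0), mh.stem(anchor))
        bb.transform(R, t)
        mh.set_backbone(bb.extract(1, len(bb)), anchor + 1)
    return True


# ----------------------------------------------------------------------
# regularizer
# ----------------------------------------------------------------------

_BOND_TERMS = (("n", "ca", "n_ca"), ("ca", "c", "ca_c"), ("c", "o", "c_o"))
_CLASH_RADII = {"n": 1.3, "ca": 1.6, "c": 1.6, "o": 1.3}


def _regularizer_penalty_grad(coords: Dict[str, np.ndarray], ca0: np.ndarray,
                              k_bond: float = 100.0, k_restraint: float = 200.0):
    """Penalty = harmonic bonded deviations from ideal geometry + backbone
    clash + flat-bottom Cα positional restraint; returns (value, grads)."""
    L = len(ca0)
    value = 0.0
    grads = {k: np.zeros_like(v) for k, v in coords.items()}

    def bond(a_name, i, b_name, j, d0):
        nonlocal value
        delta = coords[b_name][j] - coords[a_name][i]
        d = np.linalg.norm(delta)
        if d < 1e-9:
            return
        diff = d - d0
        value += k_bond * diff * diff
        g = 2.0 * k_bond * diff * delta / d
        grads[b_name][j] += g
        grads[a_name][i] -= g

    for i in range(L):
        for a, b, attr in _BOND_TERMS:
            bond(a, i, b, i, getattr(IDEAL, attr))
        if i + 1 < L:
            bond("c", i, "n", i + 1, IDEAL.c_n)

    # clash between non-bonded backbone atoms (|i-j| >= 2)
    names = list(_CLASH_RADII)
    for i in range(L):
        for j in range(i + 2, L):
            if np.linalg.norm(coords["ca"][i] - coords["ca"][j]) > 8.0:
                continue
            for a in names:
                for b in names:
                    delta = coords[b][j] - coords[a][i]
                    d = np.linalg.norm(delta)
                    rsum = _CLASH_RADII[a] + _CLASH_RADII[b]
                    if d < rsum and d > 1e-9:
                        value += (rsum - d) ** 2
                        g = -2.0 * (rsum - d) * delta / d
                        grads[b][j] += g
                        grads[a][i] -= g

    # flat-bottom CA restraint (onset 0.35 A)
    delta = coords["ca"] - ca0
    d = np.linalg.norm(delta, axis=1)
    mask = d > 0.35
    if mask.any():
        excess = d[mask] - 0.35
        value += float(k_restraint * (excess ** 2).sum())
        grads["ca"][mask] += (2.0 * k_restraint * excess / d[mask])[:, None] \
            * delta[mask]
    return value, grads


def regularize(s: Structure, cfg: Optional[PipelineConfig] = None) -> Structure:
    """Steepest-descent stereochemistry regularization.

    Restores ideal backbone bond lengths and relieves backbone clashes while
    keeping every Cα within 0.5 Å of its input position; the penalty is
    monotone non-increasing. Sidechain atoms ride rigidly with their Cα.
    """
    cfg = cfg or PipelineConfig()
    s = copy.deepcopy(s)
    for ch in s.chains:
        residues = [r for r in ch.residues if r.has_backbone()]
        if len(residues) < 2:
            continue
        coords = {name: np.array([r.atoms[name.upper()] for r in residues])
                  for name in ("n", "ca", "c", "o")}
        ca0 = coords["ca"].copy()
        value, grads = _regularizer_penalty_grad(coords, ca0)
        step = 1e-3
        for _ in range(cfg.regularizer_iterations):
            gnorm = max(np.abs(g).max() for g in grads.values())
            if gnorm < 1e-9:
                break
            accepted = False
            while step > 1e-7:
                trial = {k: v - step * grads[k] for k, v in coords.items()}
                if np.linalg.norm(trial["ca"] - ca0, axis=1).max() > 0.5:
                    step *= 0.5
                    continue
                tval, tgrads = _regularizer_penalty_grad(trial, ca0)
                if tval < value:
                    max_shift = max(
                        np.abs(trial[k] - coords[k]).max() for k in coords)
                    coords, value, grads = trial, tval, tgrads
                    accepted = True
                    step *= 1.5
                    break
                step *= 0.5
            if not accepted:
                break
            if max_shift < 0.01:
                break
        for i, r in enumerate(residues):
            shift = coords["ca"][i] - ca0[i]
            for name, pos in list(r.atoms.items()):
                if name in ("N", "CA", "C", "O"):
                    continue
                r.atoms[name] = np.asarray(pos, float) + shift
            r.atoms["N"] = coords["n"][i]
            r.atoms["CA"] = coords["ca"][i]
            r.atoms["C"] = coords["c"][i]
            r.atoms["O"] = coords["o"][i]
    return s


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def build_from_raw_model(mh: ModellingHandle, cfg: Optional[PipelineConfig],
                         lib, fdb: Optional[FragDB] = None,
                         sdb: Optional[StructureDB] = None,
                         tables: Optional[dict] = None,
                         seed: Optional[int] = None) -> Structure:
    """Run the full pipeline on a raw model: deletions → database loops →
    Monte-Carlo fallback → sidechains → regularization."""
    cfg = cfg or PipelineConfig()
    tables = tables or {}
    mh = mh.copy()
    handle_deletions(mh, cfg)
    if fdb is not None and sdb is not None and mh.gaps:
        fill_loops_by_database(mh, fdb, sdb, tables, cfg)
    if mh.gaps:
        fill_loops_monte_carlo(mh, tables.get("torsion"), tables, cfg,
                               seed=cfg.seed if seed is None else seed)
    unresolved = [g for g in mh.gaps if not (g.before < 0 or g.after >= len(mh))]
    if unresolved:
        raise ModellingError(
            "unresolved gaps: " + ", ".join(
                f"[{g.before}..{g.after}] {g.target_seq!r}" for g in unresolved))
    model = mh.to_structure()
    if lib is not None:
        model = reconstruct_sidechains(model, lib, seed=cfg.seed)
    model = regularize(model, cfg)
    return model
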
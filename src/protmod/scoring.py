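"""Environment/scorer architecture and knowledge-based potentials.

A :class:`ScoringEnvironment` holds the current (partial) model backbone
with per-residue set/unset flags and a spatial hash for neighbor queries.
Scorers evaluate a residue segment against that environment; all scores
follow a lower-is-better convention and are normalized per segment residue.

Statistical potentials are trained from a :class:`~protmod.fragdb.StructureDB`
by inverse-Boltzmann statistics with pseudo-count smoothing:

    E(bin | ctx) = -ln[(N_obs(bin, ctx) + p) / (N_ref(bin, ctx) + p)]

where the reference state is the context-free bin distribution.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import geom
from .backbone import BackboneList, reconstruct_cb
from .constants import (AA_ONE, REPULSION_CEILING, REPULSION_KNEE,
                        REPULSION_RADII)
from .fragdb import StructureDB

__all__ = [
    "ScoringEnvironment", "PairPotential", "TorsionPotential",
    "PackingPotential", "train_potentials", "score_segment", "combine",
    "fit_weights", "clash_penalty",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ONE)}

_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def clash_penalty(d: float, r_sum: float) -> float:
    """Piecewise-linear repulsion: 0 beyond ``r_sum``, rising linearly to a
    ceiling of 10 at ``REPULSION_KNEE * r_sum`` and flat below."""
    if d >= r_sum:
        return 0.0
    knee = REPULSION_KNEE * r_sum
    if d <= knee:
        return REPULSION_CEILING
    return REPULSION_CEILING * (r_sum - d) / (r_sum - knee)


# ----------------------------------------------------------------------
# environment
# ----------------------------------------------------------------------

class ScoringEnvironment:
    """Full-model backbone with set flags and a spatial hash."""

    def __init__(self, sequence: str, cell_size: float = 5.0):
        L = len(sequence)
        self.sequence = sequence
        self.n = np.full((L, 3), np.nan)
        self.ca = np.full((L, 3), np.nan)
        self.c = np.full((L, 3), np.nan)
        self.o = np.full((L, 3), np.nan)
        self.cb = np.full((L, 3), np.nan)
        self.is_set = np.zeros(L, dtype=bool)
        self.cell_size = float(cell_size)
        self._hash: Optional[Dict[tuple, List[tuple]]] = None

    def __len__(self):
        return len(self.sequence)

    @classmethod
    def from_backbone(cls, bb: BackboneList) -> "ScoringEnvironment":
        env = cls(bb.sequence)
        env.set_range(bb, 0)
        return env

    # -- updates -------------------------------------------------------
    def set_range(self, bb: BackboneList, start: int) -> "ScoringEnvironment":
        end = start + len(bb)
        if start < 0 or end > len(self):
            raise IndexError("range outside model bounds")
        self.n[start:end] = bb.n
        self.ca[start:end] = bb.ca
        self.c[start:end] = bb.c
        self.o[start:end] = bb.o
        self.cb[start:end] = bb.cb
        self.is_set[start:end] = True
        self._hash = None
        return self

    def clear_range(self, start: int, end: int) -> "ScoringEnvironment":
        if start < 0 or end > len(self):
            raise IndexError("range outside model bounds")
        for arr in (self.n, self.ca, self.c, self.o, self.cb):
            arr[start:end] = np.nan
        self.is_set[start:end] = False
        self._hash = None
        return self

    # -- neighbor queries ----------------------------------------------
    def atoms(self):
        """All atoms of set residues as ``(res_idx, atom_name, pos)``."""
        out = []
        for i in np.nonzero(self.is_set)[0]:
            for name, arr in (("N", self.n), ("CA", self.ca), ("C", self.c),
                              ("O", self.o), ("CB", self.cb)):
                pos = arr[i]
                if not np.isnan(pos).any():
                    out.append((int(i), name, pos))
        return out

    def _build_hash(self):
        h = defaultdict(list)
        cs = self.cell_size
        for entry in self.atoms():
            cell = tuple(np.floor(entry[2] / cs).astype(int))
            h[cell].append(entry)
        self._hash = dict(h)

    def query(self, pos: np.ndarray, radius: float):
        """Exact list of set-residue atoms within ``radius`` of ``pos``."""
        if self._hash is None:
            self._build_hash()
        cs = self.cell_size
        c0 = np.floor((np.asarray(pos) - radius) / cs).astype(int)
        c1 = np.floor((np.asarray(pos) + radius) / cs).astype(int)
        out = []
        for cx in range(c0[0], c1[0] + 1):
            for cy in range(c0[1], c1[1] + 1):
                for cz in range(c0[2], c1[2] + 1):
                    for entry in self._hash.get((cx, cy, cz), ()):
                        if np.linalg.norm(entry[2] - pos) <= radius:
                            out.append(entry)
        return out

    def residue_cb(self, i: int) -> np.ndarray:
        """Cβ of residue ``i``; falls back to Cα for glycine."""
        pos = self.cb[i]
        if np.isnan(pos).any():
            return self.ca[i]
        return pos

    def torsions(self, i: int) -> Tuple[float, float]:
        """(φ, ψ) of residue ``i`` from current coordinates; NaN where a
        flanking residue is unset."""
        phi = psi = np.nan
        if i > 0 and self.is_set[i - 1] and self.is_set[i]:
            phi = geom.dihedral(self.c[i - 1], self.n[i], self.ca[i], self.c[i])
        if i < len(self) - 1 and self.is_set[i] and self.is_set[i + 1]:
            psi = geom.dihedral(self.n[i], self.ca[i], self.c[i], self.n[i + 1])
        return phi, psi

    def backbone_view(self, start: int, end: int) -> BackboneList:
        if not self.is_set[start:end].all():
            raise ValueError("unset residues in range")
        return BackboneList(self.sequence[start:end], self.n[start:end],
                            self.ca[start:end], self.c[start:end],
                            self.o[start:end], self.cb[start:end])


# ----------------------------------------------------------------------
# potentials
# ----------------------------------------------------------------------

def _boltzmann_energies(obs: np.ndarray, reference: str,
                        pseudocount: float) -> np.ndarray:
    """Inverse-Boltzmann energies for an observation array whose last axis
    is the bin axis and whose leading axes are the context."""
    obs = np.asarray(obs, float)
    nbins = obs.shape[-1]
    ctx_total = obs.sum(axis=-1, keepdims=True)
    if reference == "uniform":
        ref = np.broadcast_to(ctx_total / nbins, obs.shape)
    elif reference == "marginal":
        marginal = obs.reshape(-1, nbins).sum(axis=0)
        total = marginal.sum()
        p_bin = marginal / total if total > 0 else np.full(nbins, 1.0 / nbins)
        ref = ctx_total * p_bin
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return -np.log((obs + pseudocount) / (ref + pseudocount))


class PairPotential:
    """Distance (× orientation) statistical potential keyed by an
    amino-acid pair."""

    def __init__(self, kind: str, energies: np.ndarray, dist_max: float,
                 dist_bin: float, n_angle_bins: int = 0, seq_sep_min: int = 4,
                 meta: Optional[dict] = None):
        self.kind = kind
        self.energies = np.asarray(energies, float)
        self.dist_max = float(dist_max)
        self.dist_bin = float(dist_bin)
        self.n_angle_bins = int(n_angle_bins)
        self.seq_sep_min = int(seq_sep_min)
        self.meta = meta or {}
        if not np.isfinite(self.energies).all():
            raise ValueError("non-finite potential entries")

    @classmethod
    def from_counts(cls, kind: str, counts: np.ndarray, dist_max: float,
                    dist_bin: float, n_angle_bins: int = 0,
                    seq_sep_min: int = 4, reference: str = "marginal",
                    pseudocount: float = 1.0) -> "PairPotential":
        energies = _boltzmann_energies(counts, reference, pseudocount)
        meta = {"reference": reference, "pseudocount": pseudocount,
                "counts_total": float(np.asarray(counts).sum())}
        return cls(kind, energies, dist_max, dist_bin, n_angle_bins,
                   seq_sep_min, meta)

    def dist_index(self, d: float) -> int:
        if d >= self.dist_max:
            return -1
        return int(d / self.dist_bin)

    def energy(self, aa_i: str, aa_j: str, d: float,
               angle: Optional[float] = None) -> float:
        k = self.dist_index(d)
        if k < 0:
            return 0.0
        ai = _AA_INDEX.get(aa_i)
        aj = _AA_INDEX.get(aa_j)
        if ai is None or aj is None:
            return 0.0
        if self.n_angle_bins:
            ka = min(int(angle / np.pi * self.n_angle_bins),
                     self.n_angle_bins - 1)
            return float(self.energies[ai, aj, k, ka])
        return float(self.energies[ai, aj, k])


class TorsionPotential:
    """Per-amino-acid φ/ψ grid potential (default 30° × 30° bins)."""

    def __init__(self, energies: np.ndarray, probs: np.ndarray,
                 bin_deg: float = 30.0, meta: Optional[dict] = None):
        self.energies = np.asarray(energies, float)
        self.probs = np.asarray(probs, float)
        self.bin_deg = float(bin_deg)
        self.meta = meta or {}
        if not np.isfinite(self.energies).all():
            raise ValueError("non-finite potential entries")

    @property
    def n_bins(self) -> int:
        return self.energies.shape[-1]

    def bin_of(self, angle: float) -> int:
        deg = np.degrees(geom.wrap_angle(angle)) + 180.0
        return min(int(deg / self.bin_deg), self.n_bins - 1)

    @classmethod
    def from_counts(cls, counts: np.ndarray, bin_deg: float = 30.0,
                    reference: str = "marginal",
                    pseudocount: float = 1.0) -> "TorsionPotential":
        counts = np.asarray(counts, float)
        naa = counts.shape[0]
        flat = counts.reshape(naa, -1)
        energies = _boltzmann_energies(flat, reference, pseudocount)
        probs = (flat + pseudocount)
        probs = probs / probs.sum(axis=-1, keepdims=True)
        shape = counts.shape
        return cls(energies.reshape(shape), probs.reshape(shape), bin_deg,
                   {"reference": reference, "pseudocount": pseudocount})

    def energy(self, aa: str, phi: float, psi: float) -> float:
        ai = _AA_INDEX.get(aa)
        if ai is None or np.isnan(phi) or np.isnan(psi):
            return 0.0
        return float(self.energies[ai, self.bin_of(phi), self.bin_of(psi)])

    def log_prob(self, aa: str, phi: float, psi: float) -> float:
        ai = _AA_INDEX.get(aa)
        if ai is None or np.isnan(phi) or np.isnan(psi):
            return 0.0
        return float(np.log(self.probs[ai, self.bin_of(phi), self.bin_of(psi)]))

    def sample(self, aa: str, rng: np.random.Generator) -> Tuple[float, float]:
        """Draw (φ, ψ) from the per-aa bin distribution, uniform within bin."""
        ai = _AA_INDEX.get(aa, 0)
        p = self.probs[ai].ravel()
        k = rng.choice(len(p), p=p / p.sum())
        nb = self.n_bins
        i, j = divmod(int(k), nb)
        w = np.deg2rad(self.bin_deg)
        phi = -np.pi + i * w + rng.uniform(0, w)
        psi = -np.pi + j * w + rng.uniform(0, w)
        return float(phi), float(psi)


class PackingPotential:
    """Energy as a function of the number of Cβ atoms within a cutoff."""

    def __init__(self, energies: np.ndarray, cutoff: float = 10.0,
                 max_count: int = 30, meta: Optional[dict] = None):
        self.energies = np.asarray(energies, float)
        self.cutoff = float(cutoff)
        self.max_count = int(max_count)
        self.meta = meta or {}

    @classmethod
    def from_counts(cls, counts: np.ndarray, cutoff: float = 10.0,
                    reference: str = "marginal",
                    pseudocount: float = 1.0) -> "PackingPotential":
        energies = _boltzmann_energies(counts, reference, pseudocount)
        return cls(energies, cutoff, counts.shape[-1] - 1,
                   {"reference": reference, "pseudocount": pseudocount})

    def energy(self, aa: str, count: int) -> float:
        ai = _AA_INDEX.get(aa)
        if ai is None:
            return 0.0
        return float(self.energies[ai, min(count, self.max_count)])


def train_potentials(db: StructureDB, cbeta_bins: int = 15,
                     reduced_angle_bins: int = 4, torsion_bin_deg: float = 30.0,
                     seq_sep_min: int = 4, packing_cutoff: float = 10.0,
                     packing_max: int = 30, pseudocount: float = 1.0):
    """Train the cbeta, reduced, torsion and packing tables from a database.

    Returns ``(cbeta, reduced, torsion, packing)``.
    """
    if len(db) == 0:
        raise ValueError("empty StructureDB")
    naa = len(AA_ONE)
    ntb = int(round(360.0 / torsion_bin_deg))
    cbeta_counts = np.zeros((naa, naa, cbeta_bins))
    reduced_counts = np.zeros((naa, naa, cbeta_bins, reduced_angle_bins))
    torsion_counts = np.zeros((naa, ntb, ntb))
    packing_counts = np.zeros((naa, packing_max + 1))

    tp_helper = TorsionPotential(np.zeros((naa, ntb, ntb)),
                                 np.ones((naa, ntb, ntb)), torsion_bin_deg)
    for ci in range(len(db)):
        seq = db.sequences[ci]
        co = db.coords[ci]
        L = len(seq)
        cb = np.empty((L, 3))
        for i, aa in enumerate(seq):
            cb[i] = (co[i, 1] if aa == "G"
                     else reconstruct_cb(co[i, 0], co[i, 1], co[i, 2]))
        idx = [_AA_INDEX.get(aa) for aa in seq]
        for i in range(L):
            if idx[i] is None:
                continue
            # torsion
            phi, psi = db.phi[ci][i], db.psi[ci][i]
            if not (np.isnan(phi) or np.isnan(psi)):
                torsion_counts[idx[i], tp_helper.bin_of(phi),
                               tp_helper.bin_of(psi)] += 1
            # packing: all other residues' CB within cutoff
            count = 0
            for j in range(L):
                if j != i and np.linalg.norm(cb[j] - cb[i]) <= packing_cutoff:
                    count += 1
            packing_counts[idx[i], min(count, packing_max)] += 1
            # pair terms
            for j in range(i + seq_sep_min, L):
                if idx[j] is None:
                    continue
                d_cb = np.linalg.norm(cb[j] - cb[i])
                if d_cb < cbeta_bins:
                    k = int(d_cb)
                    cbeta_counts[idx[i], idx[j], k] += 1
                    cbeta_counts[idx[j], idx[i], k] += 1
                d_ca = np.linalg.norm(co[j, 1] - co[i, 1])
                if d_ca < cbeta_bins:
                    vi = cb[i] - co[i, 1]
                    vj = cb[j] - co[j, 1]
                    if (np.linalg.norm(vi) > 1e-6
                            and np.linalg.norm(vj) > 1e-6):
                        ang = geom.angle(co[i, 1] + vi, co[i, 1],
                                         co[i, 1] + vj)
                        ka = min(int(ang / np.pi * reduced_angle_bins),
                                 reduced_angle_bins - 1)
                        k = int(d_ca)
                        reduced_counts[idx[i], idx[j], k, ka] += 1
                        reduced_counts[idx[j], idx[i], k, ka] += 1

    cbeta = PairPotential.from_counts("cbeta", cbeta_counts, cbeta_bins, 1.0,
                                      0, seq_sep_min, pseudocount=pseudocount)
    reduced = PairPotential.from_counts("reduced", reduced_counts, cbeta_bins,
                                        1.0, reduced_angle_bins, seq_sep_min,
                                        pseudocount=pseudocount)
    torsion = TorsionPotential.from_counts(torsion_counts, torsion_bin_deg,
                                           pseudocount=pseudocount)
    packing = PackingPotential.from_counts(packing_counts, packing_cutoff,
                                           pseudocount=pseudocount)
    return cbeta, reduced, torsion, packing


# ----------------------------------------------------------------------
# scorers
# ----------------------------------------------------------------------

def _pair_angle(env: ScoringEnvironment, i: int, j: int) -> Optional[float]:
    vi = env.residue_cb(i) - env.ca[i]
    vj = env.residue_cb(j) - env.ca[j]
    if np.linalg.norm(vi) < 1e-6 or np.linalg.norm(vj) < 1e-6:
        return None
    return float(np.arccos(np.clip(
        np.dot(geom.unit(vi), geom.unit(vj)), -1.0, 1.0)))


def score_segment(env: ScoringEnvironment, start: int, end: int, kind: str,
                  tables=None, constraints=None) -> float:
    """Score residues ``[start, end)`` against the environment.

    ``tables`` is the potential object required by the kind (pair potential
    for cbeta/reduced, torsion potential for torsion, packing potential for
    cb_packing); ``constraints`` is a list of ``(i, j, atom, fn)`` tuples for
    the constraint scorer. All scores are normalized by the segment length.
    """
    seg_len = end - start
    if seg_len < 1:
        raise ValueError("empty segment")
    if not env.is_set[start:end].all():
        raise ValueError("segment contains unset residues")
    seg = range(start, end)
    in_seg = lambda j: start <= j < end
    total = 0.0

    if kind in ("cbeta", "reduced"):
        pot = tables
        for i in seg:
            pi = env.residue_cb(i) if kind == "cbeta" else env.ca[i]
            for (j, aname, pos) in env.query(pi, pot.dist_max):
                if kind == "cbeta":
                    want = "CB" if not np.isnan(env.cb[j]).any() else "CA"
                else:
                    want = "CA"
                if aname != want:
                    continue
                if abs(j - i) < pot.seq_sep_min:
                    continue
                if in_seg(j) and j <= i:
                    continue
                d = float(np.linalg.norm(pos - pi))
                if kind == "reduced":
                    ang = _pair_angle(env, i, j)
                    if ang is None:
                        continue
                    total += pot.energy(env.sequence[i], env.sequence[j], d, ang)
                else:
                    total += pot.energy(env.sequence[i], env.sequence[j], d)
    elif kind == "cb_packing":
        pot = tables
        for i in seg:
            pi = env.residue_cb(i)
            count = 0
            seen = set()
            for (j, aname, pos) in env.query(pi, pot.cutoff):
                if j == i or j in seen:
                    continue
                want = "CB" if not np.isnan(env.cb[j]).any() else "CA"
                if aname != want:
                    continue
                seen.add(j)
                count += 1
            total += pot.energy(env.sequence[i], count)
    elif kind == "torsion":
        pot = tables
        for i in seg:
            phi, psi = env.torsions(i)
            total += pot.energy(env.sequence[i], phi, psi)
    elif kind == "clash":
        radii = {k: REPULSION_RADII[v] for k, v in _BACKBONE_ELEMENTS.items()}
        max_r = 2 * max(radii.values())
        for i in seg:
            for (aname, arr) in (("N", env.n), ("CA", env.ca), ("C", env.c),
                                 ("O", env.o), ("CB", env.cb)):
                pi = arr[i]
                if np.isnan(pi).any():
                    continue
                for (j, bname, pos) in env.query(pi, max_r):
                    if abs(j - i) <= 1:
                        continue  # same / peptide-bonded residue
                    if in_seg(j) and j <= i:
                        continue
                    r_sum = radii[aname] + radii[bname]
                    total += clash_penalty(float(np.linalg.norm(pos - pi)),
                                           r_sum)
    elif kind == "hbond":
        set_idx = [int(i) for i in np.nonzero(env.is_set)[0]]
        # donor H for residue j needs the preceding residue's C=O
        for i in set_idx:
            for j in set_idx:
                if abs(i - j) <= 1 or j == 0 or not env.is_set[j - 1]:
                    continue
                if not (in_seg(i) or in_seg(j)):
                    continue
                h = env.n[j] + geom.unit(env.c[j - 1] - env.o[j - 1])
                r_on = np.linalg.norm(env.o[i] - env.n[j])
                r_ch = np.linalg.norm(env.c[i] - h)
                r_oh = np.linalg.norm(env.o[i] - h)
                r_cn = np.linalg.norm(env.c[i] - env.n[j])
                if min(r_on, r_cn) < 0.5:
                    continue
                e = 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch
                                     - 1.0 / r_oh - 1.0 / r_cn)
                if e < -0.5:
                    total += float(e)
    elif kind == "constraint":
        for (i, j, atom, fn) in (constraints or []):
            if not (in_seg(i) or in_seg(j)):
                continue
            if not (env.is_set[i] and env.is_set[j]):
                continue
            if atom == "ca":
                d = float(np.linalg.norm(env.ca[i] - env.ca[j]))
            elif atom == "cb":
                d = float(np.linalg.norm(env.residue_cb(i) - env.residue_cb(j)))
            else:
                raise ValueError(f"unknown constraint atom {atom!r}")
            total += float(fn(d))
    else:
        raise ValueError(f"unknown scorer kind {kind!r}")
    return total / seg_len


def combine(scores: Dict[str, float], weights: Dict[str, float]) -> float:
    """Weighted linear combination; every weighted name must be present."""
    out = 0.0
    for name, w in weights.items():
        if name not in scores:
            raise KeyError(f"score {name!r} missing from input")
        out += w * scores[name]
    return out


def fit_weights(decoys: List[Tuple[Dict[str, float], float]],
                names: Optional[List[str]] = None) -> Dict[str, float]:
    """Least-squares weights predicting loop Cα-RMSD from score vectors.

    The intercept is fitted (on centered data) and discarded. Requires at
    least 10 decoys with at least 2 distinct RMSD labels.
    """
    if len(decoys) < 10:
        raise ValueError("need at least 10 decoys")
    rmsds = np.array([r for _, r in decoys], float)
    if len(np.unique(np.round(rmsds, 12))) < 2:
        raise ValueError("need at least 2 distinct RMSD labels")
    if names is None:
        names = sorted(decoys[0][0])
    X = np.array([[sc[n] for n in names] for sc, _ in decoys], float)
    Xc = X - X.mean(axis=0)
    yc = rmsds - rmsds.mean()
    w, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < len(names):
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    return {n: float(v) for n, v in zip(names, w)}
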
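"""Structural fragment databases.

``StructureDB`` is a linear store of chain backbones (sequence, N/Cα/C/O
coordinates, φ/ψ, 3-state secondary structure); any fragment is addressed by
``(chain_index, offset, length)``. ``FragDB`` indexes fragments by the
discretized six-descriptor geometry of their two flanking stem residues.
``fragger_search`` is a sliding-window fragment search over the store.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import geom
from .backbone import BackboneList, reconstruct_cb
from .constants import AA_ONE

__all__ = [
    "assign_ss", "StructureDB", "FragmentAddress", "StemGeometry", "FragDB",
    "stem_geometry", "fragger_search",
]

# ----------------------------------------------------------------------
# simplified Kabsch–Sander secondary structure
# ----------------------------------------------------------------------

_KS_Q = 0.084 * 332.0  # kcal/mol scaling of the electrostatic H-bond model
_KS_CUTOFF = -0.5


def _hbond_matrix(bb: BackboneList) -> np.ndarray:
    """bond[i, j] is True when the C=O of residue i accepts the amide H of
    residue j (Kabsch–Sander energy < −0.5 kcal/mol)."""
    L = len(bb)
    h = np.full((L, 3), np.nan)
    for j in range(1, L):
        h[j] = bb.n[j] + geom.unit(bb.c[j - 1] - bb.o[j - 1])
    bond = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(1, L):
            if abs(i - j) <= 1:
                continue
            r_on = np.linalg.norm(bb.o[i] - bb.n[j])
            r_ch = np.linalg.norm(bb.c[i] - h[j])
            r_oh = np.linalg.norm(bb.o[i] - h[j])
            r_cn = np.linalg.norm(bb.c[i] - bb.n[j])
            if min(r_on, r_cn) < 0.5:  # degenerate geometry guard
                continue
            e = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _KS_CUTOFF:
                bond[i, j] = True
    return bond


def kabsch_sander_energy(bb: BackboneList, i: int, j: int) -> float:
    """Kabsch–Sander H-bond energy (kcal/mol) for C=O(i) … H-N(j); +∞-like
    0.0 when the donor H is undefined (j = 0)."""
    if j < 1 or abs(i - j) <= 1:
        return 0.0
    h = bb.n[j] + geom.unit(bb.c[j - 1] - bb.o[j - 1])
    r_on = np.linalg.norm(bb.o[i] - bb.n[j])
    r_ch = np.linalg.norm(bb.c[i] - h)
    r_oh = np.linalg.norm(bb.o[i] - h)
    r_cn = np.linalg.norm(bb.c[i] - bb.n[j])
    return float(_KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def assign_ss(bb: BackboneList) -> str:
    """3-state secondary structure (H/E/C) from backbone H-bond patterns."""
    L = len(bb)
    if L < 5:
        return "C" * L
    bond = _hbond_matrix(bb)
    ss = ["C"] * L
    # alpha helix: i -> i+4 turns; residues spanned by a turn become H
    turn = [i for i in range(L - 4) if bond[i, i + 4]]
    for i in turn:
        for j in range(i + 1, i + 5):
            ss[j] = "H"
    # beta bridges (parallel / antiparallel ladders)
    for i in range(L):
        for j in range(i + 3, L):
            para = ((0 < i and i + 1 < L and bond[i - 1, j] and bond[j, i + 1])
                    or (0 < j and j + 1 < L and bond[j - 1, i] and bond[i, j + 1]))
            anti = ((bond[i, j] and bond[j, i])
                    or (0 < i and j + 1 < L and 0 < j and i + 1 < L
                        and bond[i - 1, j + 1] and bond[j - 1, i + 1]))
            if para or anti:
                if ss[i] == "C":
                    ss[i] = "E"
                if ss[j] == "C":
                    ss[j] = "E"
    return "".join(ss)


# ----------------------------------------------------------------------
# StructureDB
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentAddress:
    chain_index: int
    offset: int
    length: int


class StructureDB:
    """Linear per-chain store of backbone data."""

    def __init__(self):
        self.ids: List[str] = []
        self.chain_names: List[str] = []
        self.sequences: List[str] = []
        self.coords: List[np.ndarray] = []  # (L, 4, 3): N, CA, C, O
        self.phi: List[np.ndarray] = []
        self.psi: List[np.ndarray] = []
        self.ss: List[str] = []

    def __len__(self):
        return len(self.ids)

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.sequences)

    def add_chain(self, chain_id: str, chain_name: str, bb: BackboneList,
                  seqres: Optional[str] = None) -> int:
        """Store a chain; returns its stable index.

        If ``seqres`` is given, the backbone sequence must be a contiguous
        subsequence of it.
        """
        if seqres is not None and bb.sequence not in seqres:
            raise ValueError(
                f"backbone sequence is not a contiguous subsequence of "
                f"seqres for {chain_id}/{chain_name}")
        coords = np.stack([bb.n, bb.ca, bb.c, bb.o], axis=1)
        self.ids.append(chain_id)
        self.chain_names.append(chain_name)
        self.sequences.append(bb.sequence)
        self.coords.append(coords.astype(np.float64))
        self.phi.append(bb.phi.copy())
        self.psi.append(bb.psi.copy())
        self.ss.append(assign_ss(bb))
        return len(self.ids) - 1

    def chain_length(self, chain_index: int) -> int:
        return len(self.sequences[chain_index])

    def get_fragment(self, addr: FragmentAddress):
        """Return ``(BackboneList, sequence, ss)`` for a fragment address."""
        ci, off, length = addr.chain_index, addr.offset, addr.length
        if not (0 <= ci < len(self)):
            raise IndexError(f"chain index {ci} out of range")
        if off < 0 or length < 1 or off + length > self.chain_length(ci):
            raise IndexError(f"fragment {addr} out of chain bounds")
        seq = self.sequences[ci][off:off + length]
        co = self.coords[ci][off:off + length]
        cb = np.full((length, 3), np.nan)
        for k, aa in enumerate(seq):
            if aa != "G":
                cb[k] = reconstruct_cb(co[k, 0], co[k, 1], co[k, 2])
        bb = BackboneList(seq, co[:, 0], co[:, 1], co[:, 2], co[:, 3], cb)
        return bb, seq, self.ss[ci][off:off + length]

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            fh.write(b"PMSD")
            fh.write(struct.pack("<II", 1, len(self)))
            for k in range(len(self)):
                for text in (self.ids[k], self.chain_names[k],
                             self.sequences[k], self.ss[k]):
                    raw = text.encode()
                    fh.write(struct.pack("<I", len(raw)))
                    fh.write(raw)
                L = len(self.sequences[k])
                fh.write(struct.pack("<I", L))
                fh.write(self.coords[k].astype("<f8").tobytes())
                fh.write(self.phi[k].astype("<f8").tobytes())
                fh.write(self.psi[k].astype("<f8").tobytes())

    @classmethod
    def load(cls, path: str) -> "StructureDB":
        db = cls()
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != b"PMSD":
                raise ValueError(f"{path}: not a StructureDB file")
            version, n = struct.unpack("<II", fh.read(8))
            if version != 1:
                raise ValueError(f"{path}: unsupported version {version}")
            for _ in range(n):
                texts = []
                for _ in range(4):
                    (ln,) = struct.unpack("<I", fh.read(4))
                    texts.append(fh.read(ln).decode())
                (L,) = struct.unpack("<I", fh.read(4))
                co = np.frombuffer(fh.read(L * 4 * 3 * 8),
                                   dtype="<f8").reshape(L, 4, 3).copy()
                phi = np.frombuffer(fh.read(L * 8), dtype="<f8").copy()
                psi = np.frombuffer(fh.read(L * 8), dtype="<f8").copy()
                db.ids.append(texts[0])
                db.chain_names.append(texts[1])
                db.sequences.append(texts[2])
                db.ss.append(texts[3])
                db.coords.append(co)
                db.phi.append(phi)
                db.psi.append(psi)
        return db


# ----------------------------------------------------------------------
# stem geometry
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StemGeometry:
    l: int
    d: float
    alpha: float
    beta: float
    gamma: float
    delta: float


def _stem_frame(stem: np.ndarray):
    """Orthonormal basis from a stem's (N, CA, C): x along Cα→C, z along
    x × (Cα→N), y completing the right-handed frame."""
    n, ca, c = stem
    x = geom.unit(c - ca)
    v = n - ca
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise ValueError("collinear stem atoms")
    z = z / nz
    y = np.cross(z, x)
    return x, y, z


def _polar_azimuth(v: np.ndarray, frame) -> Tuple[float, float]:
    x, y, z = frame
    u = geom.unit(v)
    polar = float(np.arccos(np.clip(np.dot(u, z), -1.0, 1.0)))
    azimuth = float(np.arctan2(np.dot(u, y), np.dot(u, x)))
    return polar, azimuth


def stem_geometry(n_stem: np.ndarray, c_stem: np.ndarray, l: int) -> StemGeometry:
    """Six-descriptor relative geometry of two stem residues.

    ``n_stem``/``c_stem`` are (3, 3) arrays of (N, Cα, C). ``d`` is the
    distance from the N-stem C atom to the C-stem N atom; (α, β) are the
    polar/azimuth direction of that connection vector in the N-stem frame,
    (γ, δ) the direction of the reverse vector in the C-stem frame.
    """
    n_stem = np.asarray(n_stem, float)
    c_stem = np.asarray(c_stem, float)
    v = c_stem[0] - n_stem[2]  # N-stem C -> C-stem N
    d = float(np.linalg.norm(v))
    if d < 1e-8:
        return StemGeometry(l, 0.0, 0.0, 0.0, 0.0, 0.0)
    alpha, beta = _polar_azimuth(v, _stem_frame(n_stem))
    gamma, delta = _polar_azimuth(-v, _stem_frame(c_stem))
    return StemGeometry(l, d, alpha, beta, gamma, delta)


# ----------------------------------------------------------------------
# FragDB
# ----------------------------------------------------------------------

class FragDB:
    """Hash map from discretized stem geometry to fragment addresses."""

    def __init__(self, dist_bin: float = 1.0, angle_bin: float = 20.0,
                 max_pairwise_rmsd: float = 1.0):
        self.dist_bin = float(dist_bin)
        self.angle_bin = float(angle_bin)  # degrees
        self.max_pairwise_rmsd = float(max_pairwise_rmsd)
        self.buckets: Dict[tuple, List[FragmentAddress]] = {}
        self._stamp: Dict[FragmentAddress, int] = {}
        self._counter = 0

    def key(self, g: StemGeometry) -> tuple:
        ang = np.rad2deg([g.alpha, g.beta, g.gamma, g.delta])
        return (g.l, int(np.floor(g.d / self.dist_bin)),
                *(int(np.floor(a / self.angle_bin)) for a in ang))

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.buckets.values())

    # -- population ----------------------------------------------------
    @staticmethod
    def _span_backbone(db: StructureDB, chain_index: int, offset: int,
                       length: int) -> BackboneList:
        frag, _, _ = db.get_fragment(
            FragmentAddress(chain_index, offset - 1, length + 2))
        return frag

    @staticmethod
    def _stem_superposed_ca_rmsd(cand: BackboneList, ref: BackboneList) -> float:
        """Cα-RMSD over the inner residues after superposing on the stem
        (first/last residue N, Cα, C) atoms."""
        P = np.concatenate([cand.stem_atoms(0), cand.stem_atoms(len(cand) - 1)])
        Q = np.concatenate([ref.stem_atoms(0), ref.stem_atoms(len(ref) - 1)])
        R, t, _ = geom.kabsch(P, Q)
        moved = cand.ca[1:-1] @ R.T + t
        return geom.rmsd(moved, ref.ca[1:-1])

    def add_fragments(self, length: int, rmsd_thresh: float,
                      db: StructureDB) -> int:
        """Index every length-``length`` fragment whose flanking stems exist,
        skipping fragments redundant (< ``rmsd_thresh`` stem-superposed
        Cα-RMSD) with a same-bucket entry. Returns the number added."""
        if length < 1:
            raise ValueError("length must be >= 1")
        added = 0
        for ci in range(len(db)):
            Lc = db.chain_length(ci)
            for off in range(1, Lc - length):
                n_stem = db.coords[ci][off - 1, :3]
                c_stem = db.coords[ci][off + length, :3]
                try:
                    g = stem_geometry(n_stem, c_stem, length)
                except ValueError:
                    continue
                key = self.key(g)
                addr = FragmentAddress(ci, off, length)
                bucket = self.buckets.setdefault(key, [])
                redundant = False
                if rmsd_thresh > 0 and bucket:
                    cand = self._span_backbone(db, ci, off, length)
                    for other in bucket:
                        ref = self._span_backbone(db, other.chain_index,
                                                  other.offset, other.length)
                        if self._stem_superposed_ca_rmsd(cand, ref) < rmsd_thresh:
                            redundant = True
                            break
                if redundant:
                    continue
                bucket.append(addr)
                self._stamp[addr] = self._counter
                self._counter += 1
                added += 1
        return added

    # -- query ---------------------------------------------------------
    def query(self, g: StemGeometry, extra_bins: int = 0) -> List[FragmentAddress]:
        """Addresses whose keys lie within ±``extra_bins`` of ``g``'s key in
        every discretized dimension (same fragment length), ordered by
        Chebyshev bin distance then insertion order."""
        k0 = self.key(g)
        hits = []
        for key, bucket in self.buckets.items():
            if key[0] != k0[0]:
                continue
            diffs = [abs(a - b) for a, b in zip(key[1:], k0[1:])]
            cheb = max(diffs)
            if cheb <= extra_bins:
                for addr in bucket:
                    hits.append((cheb, self._stamp[addr], addr))
        hits.sort(key=lambda h: (h[0], h[1]))
        return [h[2] for h in hits]

    # -- serialization -------------------------------------------------
    def save(self, path: str) -> None:
        items = sorted(self._stamp.items(), key=lambda kv: kv[1])
        addr_key = {}
        for key, bucket in self.buckets.items():
            for addr in bucket:
                addr_key[addr] = key
        with open(path, "wb") as fh:
            fh.write(b"PMFD")
            fh.write(struct.pack("<I", 1))
            fh.write(struct.pack("<3d", self.dist_bin, self.angle_bin,
                                 self.max_pairwise_rmsd))
            fh.write(struct.pack("<I", len(items)))
            for addr, stamp in items:
                key = addr_key[addr]
                fh.write(struct.pack("<6i", *key))
                fh.write(struct.pack("<3i", addr.chain_index, addr.offset,
                                     addr.length))

    @classmethod
    def load(cls, path: str) -> "FragDB":
        with open(path, "rb") as fh:
            if fh.read(4) != b"PMFD":
                raise ValueError(f"{path}: not a FragDB file")
            (version,) = struct.unpack("<I", fh.read(4))
            if version != 1:
                raise ValueError(f"{path}: unsupported version {version}")
            dist_bin, angle_bin, max_rmsd = struct.unpack("<3d", fh.read(24))
            fdb = cls(dist_bin, angle_bin, max_rmsd)
            (n,) = struct.unpack("<I", fh.read(4))
            for _ in range(n):
                key = struct.unpack("<6i", fh.read(24))
                ci, off, length = struct.unpack("<3i", fh.read(12))
                addr = FragmentAddress(ci, off, length)
                fdb.buckets.setdefault(key, []).append(addr)
                fdb._stamp[addr] = fdb._counter
                fdb._counter += 1
        return fdb


# ----------------------------------------------------------------------
# Fragger
# ----------------------------------------------------------------------

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def fragger_search(db: StructureDB, target_seq: str,
                   target_ss: Optional[str] = None,
                   weights: Optional[Dict[str, float]] = None,
                   k: int = 10, torsion_tables=None):
    """Sliding-window fragment search.

    The per-window score is a weighted sum of mean BLOSUM62 similarity, the
    fraction of matching secondary-structure states, and mean
    ``log P(φ, ψ | aa)`` under ``torsion_tables`` (a
    :class:`~protmod.scoring.TorsionPotential`). Higher is better; returns
    the ``k`` best ``(FragmentAddress, score)``, ties broken by
    (chain, offset).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w = {"sequence": 1.0, "ss": 1.0, "torsion": 1.0}
    if weights:
        w.update(weights)
    Lw = len(target_seq)
    mat = _blosum62()
    results = []
    for ci in range(len(db)):
        Lc = db.chain_length(ci)
        seq = db.sequences[ci]
        ss = db.ss[ci]
        for off in range(Lc - Lw + 1):
            score = 0.0
            if w.get("sequence"):
                vals = [mat[target_seq[t]][seq[off + t]] for t in range(Lw)
                        if target_seq[t] in AA_ONE and seq[off + t] in AA_ONE]
                score += w["sequence"] * (float(np.mean(vals)) if vals else 0.0)
            if w.get("ss") and target_ss is not None:
                frac = sum(1 for t in range(Lw)
                           if ss[off + t] == target_ss[t]) / Lw
                score += w["ss"] * frac
            if w.get("torsion") and torsion_tables is not None:
                logs = []
                for t in range(Lw):
                    phi = db.phi[ci][off + t]
                    psi = db.psi[ci][off + t]
                    if np.isnan(phi) or np.isnan(psi):
                        continue
                    logs.append(torsion_tables.log_prob(seq[off + t], phi, psi))
                if logs:
                    score += w["torsion"] * float(np.mean(logs))
            results.append((score, ci, off))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    return [(FragmentAddress(ci, off, Lw), score)
            for score, ci, off in results[:k]]
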
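"""Peptide backbone container with synchronized Cartesian and internal
coordinates.

A :class:`BackboneList` stores N, Cα, C, O and Cβ positions per residue
together with the φ/ψ/ω torsions. Torsion edits propagate rigidly to all
downstream atoms (tree rooted at residue 0, chain direction N→C), and
chains can be (re)built from torsions alone using ideal covalent geometry.
"""

from __future__ import annotations

import numpy as np

from . import geom
from .constants import IDEAL, IdealGeometry

__all__ = [
    "BackboneList",
    "backbone_from_chain",
    "backbone_from_torsions",
    "reconstruct_cb",
    "superpose",
    "ca_rmsd",
    "ccd_close",
]

_UNDEF = np.nan


def reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                   geometry: IdealGeometry = IDEAL) -> np.ndarray:
    """Ideal tetrahedral Cβ position for a backbone frame.

    The Cβ is placed at ``geometry.ca_cb`` from Cα, symmetric with respect
    to the Cα–N and Cα–C bonds, on the side giving an L-amino acid
    (improper N–Cα–C–Cβ ≈ −122.5° for a standard frame). Chirality follows
    the handedness of the input frame.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    v_n = geom.unit(n - ca)
    v_c = geom.unit(c - ca)
    axis = np.cross(v_c, v_n)
    if np.linalg.norm(axis) < 1e-8:
        raise ValueError("collinear N, CA, C — cannot place CB")
    cos_t = np.cos(geometry.n_ca_cb)
    s = v_n + v_c
    alpha = cos_t / (1.0 + float(np.dot(v_n, v_c)))
    rest = 1.0 - alpha * alpha * float(np.dot(s, s))
    beta = np.sqrt(max(rest, 0.0)) / np.linalg.norm(axis)
    d = alpha * s + beta * axis
    return ca + geometry.ca_cb * geom.unit(d)


class BackboneList:
    """Per-residue backbone coordinates plus torsion view.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid sequence.
    n, ca, c, o, cb : ndarray of shape (L, 3)
        Atom positions in Å; ``cb`` rows are NaN for glycine.
    phi, psi, omega : ndarray of shape (L,)
        Torsions in radians; undefined entries (``phi[0]``, ``psi[-1]``,
        ``omega[0]``) are NaN.
    mode : {"ideal", "measured"}
        Whether covalent geometry is idealized or taken from coordinates.
    """

    def __init__(self, sequence, n, ca, c, o, cb, mode="measured",
                 geometry: IdealGeometry = IDEAL):
        L = len(sequence)
        if L < 1:
            raise ValueError("BackboneList needs at least one residue")
        self.sequence = str(sequence)
        self.n = np.array(n, float).reshape(L, 3)
        self.ca = np.array(ca, float).reshape(L, 3)
        self.c = np.array(c, float).reshape(L, 3)
        self.o = np.array(o, float).reshape(L, 3)
        self.cb = np.array(cb, float).reshape(L, 3)
        self.mode = mode
        self.geometry = geometry
        self.phi = np.full(L, _UNDEF)
        self.psi = np.full(L, _UNDEF)
        self.omega = np.full(L, _UNDEF)
        self.remeasure_torsions()

    def __len__(self):
        return len(self.sequence)

    def copy(self) -> "BackboneList":
        out = object.__new__(BackboneList)
        out.sequence = self.sequence
        for name in ("n", "ca", "c", "o", "cb", "phi", "psi", "omega"):
            setattr(out, name, getattr(self, name).copy())
        out.mode = self.mode
        out.geometry = self.geometry
        return out

    # ------------------------------------------------------------------
    # torsion <-> Cartesian synchronization
    # ------------------------------------------------------------------
    def remeasure_torsions(self) -> None:
        L = len(self)
        for i in range(L):
            if i > 0:
                self.phi[i] = geom.dihedral(self.c[i - 1], self.n[i],
                                            self.ca[i], self.c[i])
                self.omega[i] = geom.dihedral(self.ca[i - 1], self.c[i - 1],
                                              self.n[i], self.ca[i])
            if i < L - 1:
                self.psi[i] = geom.dihedral(self.n[i], self.ca[i],
                                            self.c[i], self.n[i + 1])

    def _downstream_rotate(self, i: int, which: str, delta: float) -> None:
        """Rigidly rotate all atoms downstream of torsion ``which`` at
        residue ``i`` by ``delta`` about the torsion axis."""
        if which == "phi":
            pivot, axis_end = self.n[i], self.ca[i]
            own = ("c", "o", "cb")
        elif which == "psi":
            pivot, axis_end = self.ca[i], self.c[i]
            own = ("o",)
        else:
            raise ValueError(f"unknown torsion {which!r}")
        R = geom.rotation_about_axis(axis_end - pivot, delta)

        def rot(p):
            return (p - pivot) @ R.T + pivot

        for name in own:
            arr = getattr(self, name)
            arr[i] = rot(arr[i])
        if i + 1 < len(self):
            for name in ("n", "ca", "c", "o", "cb"):
                arr = getattr(self, name)
                arr[i + 1:] = rot(arr[i + 1:])

    def set_torsion(self, i: int, which: str, value: float) -> "BackboneList":
        """Set φ or ψ at residue ``i``; downstream atoms rotate rigidly.

        Mutates in place and returns ``self``.
        """
        cur = {"phi": self.phi, "psi": self.psi}[which][i]
        if np.isnan(cur):
            raise ValueError(f"{which}[{i}] is undefined")
        delta = geom.wrap_angle(value - cur)
        self._downstream_rotate(i, which, delta)
        {"phi": self.phi, "psi": self.psi}[which][i] = geom.wrap_angle(value)
        return self

    # ------------------------------------------------------------------
    def transform(self, R: np.ndarray, t: np.ndarray) -> "BackboneList":
        for name in ("n", "ca", "c", "o", "cb"):
            arr = getattr(self, name)
            setattr(self, name, arr @ R.T + t)
        return self

    def extract(self, start: int, end: int) -> "BackboneList":
        """Sub-range [start, end) as a new BackboneList."""
        out = object.__new__(BackboneList)
        out.sequence = self.sequence[start:end]
        for name in ("n", "ca", "c", "o", "cb", "phi", "psi", "omega"):
            setattr(out, name, getattr(self, name)[start:end].copy())
        out.mode = self.mode
        out.geometry = self.geometry
        out.remeasure_torsions()
        return out

    def stem_atoms(self, i: int) -> np.ndarray:
        """(3, 3) array of the N, Cα, C positions of residue ``i``."""
        return np.stack([self.n[i], self.ca[i], self.c[i]])

    def heavy_atoms(self):
        """Yield ``(residue_index, atom_name, position)`` for all present
        backbone + Cβ atoms."""
        for i in range(len(self)):
            yield i, "N", self.n[i]
            yield i, "CA", self.ca[i]
            yield i, "C", self.c[i]
            yield i, "O", self.o[i]
            if not np.isnan(self.cb[i]).any():
                yield i, "CB", self.cb[i]


def backbone_from_torsions(sequence: str, phi, psi, omega=None,
                           geometry: IdealGeometry = IDEAL) -> BackboneList:
    """Build an ideal-geometry backbone from torsions.

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined); ``omega`` defaults
    to 180° everywhere. The first residue is placed in the canonical frame
    (N at origin, Cα on +x, C in the xy-plane).
    """
    L = len(sequence)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if len(phi) != L or len(psi) != L:
        raise ValueError("phi/psi length must match sequence")
    if omega is None:
        omega = np.full(L, np.pi)
    else:
        omega = np.asarray(omega, float)
        if len(omega) != L:
            raise ValueError("omega length must match sequence")

    g = geometry
    n = np.zeros((L, 3))
    ca = np.zeros((L, 3))
    c = np.zeros((L, 3))
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (g.n_ca, 0.0, 0.0)
    a = np.pi - g.n_ca_c
    c[0] = ca[0] + g.ca_c * np.array([np.cos(a), np.sin(a), 0.0])
    for i in range(1, L):
        n[i] = geom.place_atom(n[i - 1], ca[i - 1], c[i - 1],
                               g.c_n, g.ca_c_n, psi[i - 1])
        ca[i] = geom.place_atom(ca[i - 1], c[i - 1], n[i],
                                g.n_ca, g.c_n_ca, omega[i])
        c[i] = geom.place_atom(c[i - 1], n[i], ca[i],
                               g.ca_c, g.n_ca_c, phi[i])
    o = np.zeros((L, 3))
    cb = np.full((L, 3), np.nan)
    for i in range(L):
        tors = psi[i] + np.pi if i < L - 1 else np.pi
        o[i] = geom.place_atom(n[i], ca[i], c[i], g.c_o, g.ca_c_o, tors)
        if sequence[i] != "G":
            cb[i] = reconstruct_cb(n[i], ca[i], c[i], g)
    return BackboneList(sequence, n, ca, c, o, cb, mode="ideal", geometry=g)


def backbone_from_chain(structure, chain_id: str, span=None) -> BackboneList:
    """Extract a BackboneList from a :class:`~protmod.io_formats.Structure`
    chain (measured-geometry mode). ``span`` is a 0-based ``(start, end)``
    residue-index range, end exclusive; default whole chain."""
    chain = structure.chain(chain_id)
    residues = chain.residues
    if span is None:
        span = (0, len(residues))
    start, end = span
    residues = residues[start:end]
    seq = []
    n, ca, c, o, cb = [], [], [], [], []
    for r in residues:
        for name in ("N", "CA", "C", "O"):
            if name not in r.atoms:
                raise ValueError(
                    f"residue {r.name} {r.number}{r.insertion_code} misses "
                    f"backbone atom {name}")
        seq.append(r.one_letter)
        n.append(r.atoms["N"])
        ca.append(r.atoms["CA"])
        c.append(r.atoms["C"])
        o.append(r.atoms["O"])
        if r.one_letter == "G":
            cb.append((np.nan,) * 3)
        elif "CB" in r.atoms:
            cb.append(r.atoms["CB"])
        else:
            cb.append(reconstruct_cb(np.asarray(r.atoms["N"]),
                                     np.asarray(r.atoms["CA"]),
                                     np.asarray(r.atoms["C"])))
    return BackboneList("".join(seq), n, ca, c, o, cb, mode="measured")


def _gather(bb: BackboneList, atoms):
    cols = []
    for name in atoms:
        cols.append(getattr(bb, name if name != "n" else "n"))
    return np.concatenate(cols, axis=0)


def superpose(mobile: BackboneList, ref: BackboneList, atoms=("n", "ca", "c")):
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)``; the transform is *not* applied to ``mobile``.
    """
    if len(mobile) != len(ref):
        raise ValueError("length mismatch")
    P = _gather(mobile, atoms)
    Q = _gather(ref, atoms)
    return geom.kabsch(P, Q)


def ca_rmsd(a: BackboneList, b: BackboneList, superposed: bool = False) -> float:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if superposed:
        R, t, _ = geom.kabsch(a.ca, b.ca)
        return geom.rmsd(a.ca @ R.T + t, b.ca)
    return geom.rmsd(a.ca, b.ca)


def _ccd_torsions(L: int):
    """Sweep order: ψ(0), then φ/ψ per residue N→C, ending with φ(L−1)."""
    out = [(0, "psi")]
    for i in range(1, L - 1):
        out.append((i, "phi"))
        out.append((i, "psi"))
    if L > 1:
        out.append((L - 1, "phi"))
    return out


def ccd_close(loop: BackboneList, n_anchor: np.ndarray, c_anchor: np.ndarray,
              max_iter: int = 200, tol: float = 0.1):
    """Cyclic-coordinate-descent closure of ``loop`` onto two anchors.

    ``n_anchor`` and ``c_anchor`` are (3, 3) arrays holding the N, Cα, C
    positions of the anchoring residues. The loop's first residue is rigidly
    placed onto ``n_anchor`` and then φ/ψ torsions are swept N→C, each set
    to the closed-form angle minimizing the squared distance of the loop's
    last-residue (N, Cα, C) to ``c_anchor``.

    Returns ``(closed_loop, converged, anchor_rmsd)``. The input loop is not
    modified.
    """
    if len(loop) < 3:
        raise ValueError("loop must have at least 3 residues")
    loop = loop.copy()
    n_anchor = np.asarray(n_anchor, float)
    c_anchor = np.asarray(c_anchor, float)

    R, t, _ = geom.kabsch(loop.stem_atoms(0), n_anchor)
    loop.transform(R, t)

    L = len(loop)
    torsions = _ccd_torsions(L)

    def anchor_rmsd():
        return geom.rmsd(loop.stem_atoms(L - 1), c_anchor)

    best = anchor_rmsd()
    if best <= tol:
        return loop, True, best

    converged = False
    for _ in range(max_iter):
        for (i, which) in torsions:
            if which == "phi":
                pivot, axis_end = loop.n[i], loop.ca[i]
            else:
                pivot, axis_end = loop.ca[i], loop.c[i]
            axis = axis_end - pivot
            nrm = np.linalg.norm(axis)
            if nrm < 1e-9:
                continue
            u = axis / nrm
            # moving subset of the three target atoms for this torsion
            if i < L - 1:
                moving = loop.stem_atoms(L - 1)
                target = c_anchor
            else:  # phi of the last residue only moves its own C
                moving = loop.c[L - 1][None, :]
                target = c_anchor[2][None, :]
            rel = moving - pivot
            along = rel @ u
            proj = pivot + along[:, None] * u
            r = moving - proj
            f = target - proj
            a = float((r * f).sum())
            b = float((np.cross(np.broadcast_to(u, r.shape), r) * f).sum())
            if abs(a) < 1e-15 and abs(b) < 1e-15:
                continue
            theta = np.arctan2(b, a)
            if abs(theta) < 1e-12:
                continue
            loop._downstream_rotate(i, which, theta)
        val = anchor_rmsd()
        if val <= tol:
            converged = True
            break
    loop.remeasure_torsions()
    return loop, converged, anchor_rmsd()
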
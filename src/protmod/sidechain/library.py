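"""Rotamer libraries.

Two text dialects are supported: the Dunbrack 2010 backbone-dependent
(bbdep) table and a compact backbone-independent dialect used for the
bundled miniature library. Entries per key are kept sorted by descending
probability and renormalized to sum to 1.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..constants import THREE_TO_ONE

__all__ = ["RotamerLibrary", "read_bbdep_library", "read_library",
           "write_library", "load_mini_library"]

Entry = Tuple[float, np.ndarray, np.ndarray]  # prob, chi means, chi sigmas


def _normalize(entries: List[Entry]) -> List[Entry]:
    entries = sorted(entries, key=lambda e: -e[0])
    total = sum(e[0] for e in entries)
    if total <= 0:
        raise ValueError("non-positive probability mass")
    return [(p / total, c, s) for p, c, s in entries]


class RotamerLibrary:
    """Backbone-dependent and/or backbone-independent rotamer entries."""

    def __init__(self, grid_deg: float = 10.0):
        self.grid_deg = float(grid_deg)
        self.bbdep: Dict[Tuple[str, int, int], List[Entry]] = {}
        self.indep: Dict[str, List[Entry]] = {}

    def _bin(self, angle_rad: float) -> int:
        deg = np.degrees(angle_rad)
        g = self.grid_deg
        b = int(np.round(deg / g) * g)
        while b >= 180:
            b -= 360
        while b < -180:
            b += 360
        return b

    def add_bbdep(self, aa: str, phi_deg: int, psi_deg: int, prob: float,
                  chis, sigmas) -> None:
        key = (aa, int(phi_deg), int(psi_deg))
        self.bbdep.setdefault(key, []).append(
            (float(prob), np.asarray(chis, float), np.asarray(sigmas, float)))

    def add_indep(self, aa: str, prob: float, chis, sigmas) -> None:
        self.indep.setdefault(aa, []).append(
            (float(prob), np.asarray(chis, float), np.asarray(sigmas, float)))

    def normalize(self) -> "RotamerLibrary":
        self.bbdep = {k: _normalize(v) for k, v in self.bbdep.items()}
        self.indep = {k: _normalize(v) for k, v in self.indep.items()}
        return self

    def get(self, aa: str, phi: Optional[float],
            psi: Optional[float]) -> List[Entry]:
        """Entries for an amino acid at (φ, ψ) in radians; termini (None or
        NaN torsions) and missing bins fall back to the backbone-independent
        table."""
        if (phi is not None and psi is not None
                and not (np.isnan(phi) or np.isnan(psi))):
            key = (aa, self._bin(phi), self._bin(psi))
            if key in self.bbdep:
                return self.bbdep[key]
        return self.indep.get(aa, [])


def read_bbdep_library(path: str) -> RotamerLibrary:
    """Read a Dunbrack-2010-style backbone-dependent text table.

    Expected columns: aa(3-letter), φ, ψ, count, r1..r4, probability,
    χ1..χ4 means, χ1..χ4 sigmas.
    """
    lib = RotamerLibrary()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 17:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 17 columns, got {len(parts)}")
            aa3 = parts[0].upper()
            if aa3 not in THREE_TO_ONE:
                raise ValueError(f"{path}:{lineno}: unknown amino acid {aa3!r}")
            try:
                phi = int(round(float(parts[1])))
                psi = int(round(float(parts[2])))
                prob = float(parts[8])
                chis = [float(x) for x in parts[9:13]]
                sigmas = [float(x) for x in parts[13:17]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            lib.add_bbdep(THREE_TO_ONE[aa3], phi, psi, prob, chis, sigmas)
    return lib.normalize()


def read_library(path_or_lines) -> RotamerLibrary:
    """Read the compact backbone-independent dialect: per line
    ``AA prob chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4``."""
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    lib = RotamerLibrary()
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 10:
            raise ValueError(f"line {lineno}: expected 10 columns")
        aa = parts[0].upper()
        lib.add_indep(aa, float(parts[1]),
                      [float(x) for x in parts[2:6]],
                      [float(x) for x in parts[6:10]])
    return lib.normalize()


def write_library(lib: RotamerLibrary, path: str) -> None:
    """Write the backbone-independent entries in the compact dialect."""
    with open(path, "w") as fh:
        fh.write("# AA prob chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4\n")
        for aa in sorted(lib.indep):
            for prob, chis, sigmas in lib.indep[aa]:
                c = list(chis) + [0.0] * (4 - len(chis))
                s = list(sigmas) + [0.0] * (4 - len(sigmas))
                fh.write(f"{aa} {prob:.8f} "
                         + " ".join(f"{x:.6f}" for x in c) + " "
                         + " ".join(f"{x:.6f}" for x in s) + "\n")


def load_mini_library() -> RotamerLibrary:
    """The bundled miniature backbone-independent library (fixture data)."""
    text = (resources.files("protmod") / "data" / "mini_rotamers.txt").read_text()
    return read_library(text.splitlines())
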
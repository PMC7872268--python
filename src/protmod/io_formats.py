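"""Structure and alignment I/O.

Reads a pragmatic subset of PDB (ATOM/TER/END, first model, altloc resolved
to highest occupancy) and of mmCIF (the ``atom_site`` loop only). Writes the
PDB dialect. Alignments are multi-FASTA with ``-`` gaps; a row can be
attached to a structure chain, giving a column → residue-index map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO

from .constants import BACKBONE_ATOMS, THREE_TO_ONE

__all__ = [
    "Residue", "Chain", "Structure", "Alignment", "FormatError",
    "read_structure", "write_structure", "read_fasta_alignment",
    "attach_view",
]


class FormatError(ValueError):
    """Raised when an input file does not parse in the named dialect."""


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str  # 3-letter code
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)
    occupancy: Dict[str, float] = field(default_factory=dict)
    bfactor: Dict[str, float] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def one_letter_sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Structure:
    chains: List[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")


class Alignment:
    """Gapped sequence rows; row 0 is the target by convention."""

    def __init__(self, rows: List[str], names: Optional[List[str]] = None):
        if len(rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        length = len(rows[0])
        for i, r in enumerate(rows):
            if not r:
                raise FormatError(f"alignment row {i} is empty")
            if len(r) != length:
                raise FormatError(
                    f"alignment rows have unequal lengths ({len(r)} vs {length})")
        self.rows = [r.upper() for r in rows]
        self.names = names or [f"seq{i}" for i in range(len(rows))]
        # row -> (structure, chain_id, {column: residue_index})
        self.attachments: Dict[int, Tuple[Structure, str, Dict[int, int]]] = {}

    def __len__(self):
        return len(self.rows[0])

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")


# ----------------------------------------------------------------------
# PDB
# ----------------------------------------------------------------------

def _assemble(records, source: str) -> Structure:
    """Build a Structure from raw atom records, resolving altlocs and
    dropping incomplete residues / empty chains.

    ``records``: list of (chain, resnum, icode, resname, atom, altloc,
    xyz, occ, bfac) in file order.
    """
    # altloc resolution: highest occupancy, ties by altloc letter order
    best = {}
    order = []
    for rec in records:
        chain, resnum, icode, resname, atom, altloc, xyz, occ, bfac = rec
        key = (chain, resnum, icode, resname, atom)
        if key not in best:
            best[key] = (altloc, occ, xyz, bfac)
            order.append(key)
        else:
            cur_alt, cur_occ, _, _ = best[key]
            if occ > cur_occ or (occ == cur_occ and altloc < cur_alt):
                best[key] = (altloc, occ, xyz, bfac)

    structure = Structure()
    chain_map: Dict[str, Chain] = {}
    res_map: Dict[Tuple[str, int, str, str], Residue] = {}
    for key in order:
        chain_id, resnum, icode, resname, atom = key
        altloc, occ, xyz, bfac = best[key]
        if chain_id not in chain_map:
            chain_map[chain_id] = Chain(chain_id)
            structure.chains.append(chain_map[chain_id])
        rkey = (chain_id, resnum, icode, resname)
        if rkey not in res_map:
            res = Residue(resnum, icode, resname)
            res_map[rkey] = res
            chain_map[chain_id].residues.append(res)
        res = res_map[rkey]
        res.atoms[atom] = np.asarray(xyz, float)
        res.occupancy[atom] = occ
        res.bfactor[atom] = bfac

    kept_chains = []
    for ch in structure.chains:
        ch.residues = [r for r in ch.residues if r.has_backbone()]
        if ch.residues:
            kept_chains.append(ch)
        else:
            warnings.warn(
                f"{source}: chain {ch.id!r} has no complete backbone "
                f"residue; dropped")
    structure.chains = kept_chains
    return structure


def _read_pdb(path: str) -> Structure:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "ENDMDL":
                break  # first model only
            if rec != "ATOM  ":
                continue
            try:
                atom = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                resnum = int(line[22:26])
                icode = line[26].strip()
                xyz = (float(line[30:38]), float(line[38:46]),
                       float(line[46:54]))
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
            records.append((chain, resnum, icode, resname, atom, altloc,
                            xyz, occ, bfac))
    return _assemble(records, path)


def _cif_tokens(line: str) -> List[str]:
    """Whitespace tokenization with minimal quote support."""
    tokens = []
    i = 0
    n = len(line)
    while i < n:
        if line[i].isspace():
            i += 1
            continue
        if line[i] in "'\"":
            q = line[i]
            j = line.find(q, i + 1)
            if j < 0:
                raise FormatError(f"unterminated quote in: {line!r}")
            tokens.append(line[i + 1:j])
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tokens.append(line[i:j])
            i = j
    return tokens


def _read_mmcif(path: str) -> Structure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    # locate the atom_site loop
    tags: List[str] = []
    rows: List[List[str]] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            j = i + 1
            block_tags = []
            while j < len(lines) and lines[j].strip().startswith("_"):
                block_tags.append(lines[j].strip().split()[0])
                j += 1
            if block_tags and block_tags[0].startswith("_atom_site."):
                tags = block_tags
                while j < len(lines):
                    stripped = lines[j].strip()
                    if (not stripped or stripped.startswith("_")
                            or stripped.startswith("loop_")
                            or stripped.startswith("#")
                            or stripped.startswith("data_")):
                        break
                    rows.append(_cif_tokens(stripped))
                    j += 1
                break
            i = j
        else:
            i += 1
    if not tags:
        raise FormatError(f"{path}: no _atom_site loop found")
    idx = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}

    def get(row, *names, default=None):
        for nm in names:
            if nm in idx and idx[nm] < len(row):
                v = row[idx[nm]]
                if v not in (".", "?"):
                    return v
        return default

    records = []
    first_model = None
    for lineno, row in enumerate(rows, 1):
        try:
            if get(row, "group_PDB", default="ATOM") != "ATOM":
                continue
            model = get(row, "pdbx_PDB_model_num", default="1")
            if first_model is None:
                first_model = model
            elif model != first_model:
                continue
            atom = get(row, "auth_atom_id", "label_atom_id")
            resname = get(row, "auth_comp_id", "label_comp_id")
            chain = get(row, "auth_asym_id", "label_asym_id")
            resnum = int(get(row, "auth_seq_id", "label_seq_id"))
            icode = get(row, "pdbx_PDB_ins_code", default="") or ""
            altloc = get(row, "label_alt_id", default="") or ""
            xyz = (float(get(row, "Cartn_x")), float(get(row, "Cartn_y")),
                   float(get(row, "Cartn_z")))
            occ = float(get(row, "occupancy", default="1.0"))
            bfac = float(get(row, "B_iso_or_equiv", default="0.0"))
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: atom_site row {lineno}: {exc}") from exc
        records.append((chain, resnum, icode, resname, atom, altloc,
                        xyz, occ, bfac))
    return _assemble(records, path)


def read_structure(path: str, dialect: str = "pdb") -> Structure:
    """Read a structure file; ``dialect`` is ``"pdb"`` or ``"mmcif"``."""
    if dialect == "pdb":
        return _read_pdb(path)
    if dialect == "mmcif":
        return _read_mmcif(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# canonical intra-residue atom output order
_ATOM_ORDER = {name: i for i, name in enumerate(
    ("N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "OG", "OG1", "SG",
     "CD", "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD",
     "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
     "CZ", "CZ2", "CZ3", "NZ", "CH2", "NH1", "NH2", "OH", "OXT"))}


def write_structure(s: Structure, path: str, dialect: str = "pdb") -> None:
    """Write a structure in the PDB dialect (ATOM/TER/END subset)."""
    if dialect != "pdb":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    lines = []
    serial = 1
    for ch in s.chains:
        for r in ch.residues:
            if r.number > 9999 or r.number < -999:
                raise ValueError(
                    f"residue number {r.number} out of PDB range")
            names = sorted(r.atoms, key=lambda a: (_ATOM_ORDER.get(a, 99), a))
            for aname in names:
                pos = np.asarray(r.atoms[aname], float)
                if not np.isfinite(pos).all():
                    raise ValueError(
                        f"non-finite coordinate at residue "
                        f"{r.name} {r.number}{r.insertion_code} atom {aname}")
                if len(aname) < 4:
                    field_name = f" {aname:<3s}"
                else:
                    field_name = f"{aname:<4s}"
                occ = r.occupancy.get(aname, 1.0)
                bfac = r.bfactor.get(aname, 0.0)
                element = aname.strip().lstrip("0123456789")[0]
                lines.append(
                    f"ATOM  {serial:5d} {field_name} {r.name:>3s} {ch.id}"
                    f"{r.number:4d}{r.insertion_code or ' '}   "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"{occ:6.2f}{bfac:6.2f}          {element:>2s}")
                serial += 1
        last = ch.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {ch.id}"
            f"{last.number:4d}{last.insertion_code or ' '}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# FASTA alignments
# ----------------------------------------------------------------------

def read_fasta_alignment(path: str) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: need at least 2 FASTA records")
    rows = [str(rec.seq).upper() for rec in records]
    names = [rec.id for rec in records]
    for nm, row in zip(names, rows):
        if not row:
            raise FormatError(f"{path}: empty record {nm!r}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return Alignment(rows, names)


def attach_view(aln: Alignment, row: int, s: Structure, chain_id: str) -> Alignment:
    """Bind alignment ``row`` to a structure chain.

    The ungapped row must equal the chain's one-letter sequence or match a
    unique contiguous subsequence of it. Populates the column → residue-index
    map for every non-gap column.
    """
    seq = aln.ungapped(row)
    chain_seq = s.chain(chain_id).one_letter_sequence
    offsets = []
    start = chain_seq.find(seq)
    while start != -1:
        offsets.append(start)
        start = chain_seq.find(seq, start + 1)
    if not offsets:
        k = next((i for i, (a, b) in enumerate(zip(seq, chain_seq))
                  if a != b), min(len(seq), len(chain_seq)))
        raise ValueError(
            f"row {row} does not match chain {chain_id!r}: first mismatch "
            f"at ungapped position {k} "
            f"({seq[k:k+1] or '?'} vs {chain_seq[k:k+1] or '?'})")
    if len(offsets) > 1:
        raise ValueError(
            f"row {row} matches chain {chain_id!r} at multiple offsets "
            f"{offsets}; ambiguous")
    offset = offsets[0]
    colmap = {}
    k = 0
    for col, letter in enumerate(aln.rows[row]):
        if letter != "-":
            colmap[col] = offset + k
            k += 1
    aln.attachments[row] = (s, chain_id, colmap)
    return aln
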
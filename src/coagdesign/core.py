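"""Core domain types and file I/O for peptide-receptor complex analysis.

The in-memory model is deliberately simple: a :class:`Structure` is an
ordered list of :class:`AtomRecord` (names, residue identity, simplified
force-field parameters) plus an ``(n_atoms, 3)`` coordinate array in
Angstrom; a :class:`Trajectory` shares one topology across ordered frames.
Residue numbering is 1-based and taken verbatim from the input — positional
mutation notation such as "S16W" depends on author numbering, so nothing
here ever renumbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Standard atomic masses (Da) for the elements the simplified topology uses.
ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass(frozen=True)
class PeptideSequence:
    """A 1-based amino-acid sequence with mutation provenance.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    residues : str
        One-letter codes; position ``i`` (1-based) is ``residues[i-1]``.
    provenance : tuple of str
        Labels of design operations applied so far, e.g. ``("S16W", "graft:GLP1[30:31]")``.
    """

    id: str
    residues: str
    provenance: tuple = ()

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_AA:
                raise ValidationError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based *position*."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]


@dataclass
class AtomRecord:
    """One atom of the simplified topology.

    ``partial_charge`` is in elementary charge units, ``lj_sigma`` in
    Angstrom, ``lj_epsilon`` in kJ/mol, ``mass`` in Da. Fresh atoms from a
    PDB carry zero charge/LJ placeholders until :func:`assign_params`.
    """

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    partial_charge: float = 0.0
    lj_sigma: float = 3.5
    lj_epsilon: float = 0.0
    mass: float = 12.011

    def validate(self) -> None:
        if not (self.lj_sigma > 0 and self.lj_epsilon >= 0 and self.mass > 0):
            raise ValidationError(f"atom {self.atom_name}: non-physical parameters")
        vals = (self.partial_charge, self.lj_sigma, self.lj_epsilon, self.mass)
        if not all(np.isfinite(vals)):
            raise ValidationError(f"atom {self.atom_name}: non-finite parameters")

    @property
    def residue_key(self) -> tuple:
        """(chain_id, residue_index) — unique residue identity in a complex."""
        return (self.chain_id, self.residue_index)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Structure:
    """Atoms plus one coordinate set (Angstrom)."""

    atoms: list
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atoms) == 0:
            raise ValidationError("structure has no atoms")
        if self.coords.shape != (len(self.atoms), 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list:
        """Unique (chain, residue_index) keys in first-appearance order."""
        seen, out = set(), []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a.residue_key)
        return out

    def atom_indices(self, chain_id=None, residue_index=None, atom_name=None,
                     heavy_only=False) -> np.ndarray:
        """Indices of atoms matching the given filters."""
        idx = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_index is not None and a.residue_index != residue_index:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if heavy_only and not a.is_heavy:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def copy(self) -> "Structure":
        return Structure([dataclasses.replace(a) for a in self.atoms], self.coords.copy())


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frame_interval`` (ps) is metadata only; all analyses weight frames
    equally.
    """

    topology: list
    frames: np.ndarray
    frame_interval: float = 2.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("trajectory needs >= 1 frame of shape (n_atoms, 3)")
        if self.frames.shape[1:] != (len(self.topology), 3):
            raise ValidationError(
                f"frame shape {self.frames.shape[1:]} does not match "
                f"{len(self.topology)} topology atoms"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.frames[i])


_VALID_LABELS = {"ECD", "TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7",
                 "ECL1", "ECL2", "ECL3", "ICL1", "ICL2", "ICL3", "CTR", "other"}


@dataclass
class ReceptorAnnotation:
    """Receptor domain labels (ECD / TM1-7 / ECL1-3 / ICL1-3 / CTR) over
    residue-index ranges; residues outside every range are "other"."""

    segments: list  # of (start, end, label)

    def __post_init__(self):
        spans = []
        for start, end, label in self.segments:
            if label not in _VALID_LABELS:
                raise ValidationError(f"unknown domain label {label!r}")
            if start > end:
                raise ValidationError(f"segment {label}: start {start} > end {end}")
            spans.append((int(start), int(end), label))
        spans.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"overlapping segments {l1} [{s1},{e1}] and {l2} [{s2},{e2}]"
                )
        self.segments = spans

    def label(self, residue_index: int) -> str:
        for start, end, lab in self.segments:
            if start <= residue_index <= end:
                return lab
        return "other"

    def domains(self) -> list:
        """Distinct labels in segment order, 'other' appended last."""
        out = []
        for _, _, lab in self.segments:
            if lab not in out:
                out.append(lab)
        out.append("other")
        return out


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _element_of(atom_name: str, element_hint: str = "") -> str:
    if element_hint:
        return element_hint.strip().capitalize().upper() if len(element_hint.strip()) == 1 \
            else element_hint.strip().upper()
    name = atom_name.strip()
    return name[0].upper() if name else "C"


def _structure_from_atom_array(arr) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        el = str(arr.element[i]) if arr.element[i] else _element_of(str(arr.atom_name[i]))
        atoms.append(AtomRecord(
            atom_name=str(arr.atom_name[i]),
            element=el,
            residue_index=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]) or "A",
            mass=ELEMENT_MASS.get(el, 12.011),
        ))
    return Structure(atoms, np.asarray(arr.coord, dtype=float))


def read_pdb(path, multi_model: bool = False):
    """Read a PDB file into a :class:`Structure` (or :class:`Trajectory` if
    *multi_model*).

    Residue indices come verbatim from PDB numbering; charges and LJ
    parameters are zero/neutral placeholders until :func:`assign_params`.
    Altloc and insertion codes are rejected with a clear error.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
    except Exception as exc:  # biotite raises several exception types
        raise PDBParseError(f"{path}: {exc}") from exc

    # reject altloc / insertion codes up front (out of scope by design)
    for line in pdb_file.lines:
        if line.startswith(("ATOM", "HETATM")):
            if len(line) > 16 and line[16] not in (" ", ""):
                raise PDBParseError(f"{path}: altloc codes are not supported ({line[:27]!r})")
            if len(line) > 26 and line[26] not in (" ", ""):
                raise PDBParseError(f"{path}: insertion codes are not supported ({line[:27]!r})")

    try:
        if multi_model:
            stack = pdb_file.get_structure(model=None)
        else:
            arr = pdb_file.get_structure(model=1)
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    if multi_model:
        first = stack[0]
        struct = _structure_from_atom_array(first)
        return Trajectory(struct.atoms, np.asarray(stack.coord, dtype=float))
    return _structure_from_atom_array(arr)


def write_pdb(obj, path) -> Path:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks).

    Round trip through :func:`read_pdb` preserves atom names, residue
    indices and coordinates to PDB precision (1e-3 A).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if isinstance(obj, Trajectory):
        topo, coord_sets = obj.topology, obj.frames
    elif isinstance(obj, Structure):
        topo, coord_sets = obj.atoms, obj.coords[None]
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if len(topo) == 0:
        raise ValidationError("refusing to write an empty atom list")

    n = len(topo)
    template = struc.AtomArray(n)
    template.coord = np.zeros((n, 3))
    template.chain_id = np.array([a.chain_id for a in topo])
    template.res_id = np.array([a.residue_index for a in topo])
    template.res_name = np.array([a.residue_name for a in topo])
    template.atom_name = np.array([a.atom_name for a in topo])
    template.element = np.array([a.element for a in topo])
    template.hetero = np.zeros(n, dtype=bool)

    if coord_sets.shape[0] == 1:
        template.coord = np.asarray(coord_sets[0], dtype=float)
        out = template
    else:
        out = struc.stack([template] * coord_sets.shape[0])
        out.coord = np.asarray(coord_sets, dtype=float)

    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(out)
    path = Path(path)
    pdb_file.write(str(path))
    return path


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read FASTA records as :class:`PeptideSequence`, order preserved."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, aa in enumerate(seq, start=1):
            if aa not in CANONICAL_AA:
                raise ValidationError(
                    f"record {rec.id!r}: non-canonical residue {aa!r} at position {pos}"
                )
        out.append(PeptideSequence(id=rec.id, residues=seq))
    return out


def write_fasta(seqs: Iterable[PeptideSequence], path) -> Path:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    seqio_write(records, str(path), "fasta")
    return Path(path)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> ReceptorAnnotation:
    """Read a receptor domain table: TSV columns start, end, label.

    A header row is optional (detected by a non-numeric first field).
    """
    segments = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(f"{path}:{ln}: expected 3 tab-separated fields")
            if ln == 1 and not parts[0].lstrip("-").isdigit():
                continue  # header
            segments.append((int(parts[0]), int(parts[1]), parts[2]))
    return ReceptorAnnotation(segments)


def write_annotation(annotation: ReceptorAnnotation, path) -> Path:
    with open(path, "w") as fh:
        fh.write("start\tend\tlabel\n")
        for start, end, label in annotation.segments:
            fh.write(f"{start}\t{end}\t{label}\n")
    return Path(path)
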
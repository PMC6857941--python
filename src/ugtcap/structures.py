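"""Atomic structures and PDB/PDBQT file handling.

Receptors are read from single-model PDB or PDBQT files; docked ligand
conformations come in multi-MODEL files (one MODEL...ENDMDL block per docking
run, the layout produced when poses are extracted from an AutoDock log).
Coordinates are in Angstroms throughout; residue numbering follows the input
file (author numbering, 1-based), and insertion codes are preserved in the
residue keys.

Alternate locations: atoms with altloc 'A' or blank are kept, all others are
dropped with a warning, so every retained (chain, residue, name) is unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError

__all__ = [
    "Atom",
    "Pose",
    "PoseSet",
    "ReceptorStructure",
    "read_receptor",
    "read_poses",
    "write_receptor",
    "write_poses",
]

# AutoDock atom types that are not plain element symbols.
_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C",   # aromatic carbon
    "OA": "O",  # H-bond accepting oxygen
    "NA": "N",
    "SA": "S",
    "HD": "H",  # polar hydrogen
    "HS": "H",
    "NS": "N",
    "OS": "O",
    "CL": "Cl",
    "BR": "Br",
}

_KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Se",
}


@dataclass
class Atom:
    """One atom record: identity plus a 3-vector position in Angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    altloc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.icode)


@dataclass
class Pose:
    """One docked ligand conformation.

    ``bonds`` is a list of unordered atom-index pairs; empty means no explicit
    bond records were present and connectivity must be inferred.
    """

    atoms: list[Atom]
    pose_index: int = 1
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms if a.is_heavy])


@dataclass
class PoseSet:
    """All poses of one ligand; atom count and ordering match across poses."""

    ligand_id: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("PoseSet requires at least one pose")
        names = [a.name for a in self.poses[0].atoms]
        for pose in self.poses[1:]:
            if [a.name for a in pose.atoms] != names:
                raise ValueError(
                    "poses differ in atom count or ordering within PoseSet"
                )
        seen = set()
        for pose in self.poses:
            if pose.pose_index in seen:
                raise ValueError(f"duplicate pose_index {pose.pose_index}")
            seen.add(pose.pose_index)

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class ReceptorStructure:
    """A receptor: atoms plus an index from residue key to atom indices."""

    atoms: list[Atom]
    residue_index: dict[tuple[str, int, str], list[int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.residue_index:
            self.residue_index = _build_residue_index(self.atoms)

    def residue_atoms(self, key: tuple[str, int, str]) -> list[Atom]:
        return [self.atoms[i] for i in self.residue_index[key]]

    def find_residue(self, residue_number: int) -> list[tuple[str, int, str]]:
        """All residue keys with the given author residue number."""
        return [k for k in self.residue_index if k[1] == residue_number]


def _build_residue_index(
    atoms: Sequence[Atom],
) -> dict[tuple[str, int, str], list[int]]:
    index: dict[tuple[str, int, str], list[int]] = {}
    for i, atom in enumerate(atoms):
        index.setdefault(atom.residue_key, []).append(i)
    return index


def _element_from_fields(
    name: str, element_field: str, dialect: str
) -> str:
    """Infer the element from the element/type column, else the atom name."""
    token = element_field.strip()
    if token:
        if dialect == "pdbqt":
            mapped = _PDBQT_TYPE_TO_ELEMENT.get(token.upper())
            if mapped:
                return mapped
        cand = token[0].upper() + token[1:].lower()
        if cand in _KNOWN_ELEMENTS:
            return cand
    # Fall back to the atom name: first alphabetic character(s).
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return ""
    two = stripped[0].upper() + stripped[1:2].lower()
    if two in _KNOWN_ELEMENTS and two not in {"Cl", "Br", "Se"}:
        # single-letter match is preferred unless a true two-letter element
        pass
    if two in {"Cl", "Br", "Se"} and two in _KNOWN_ELEMENTS:
        return two
    one = stripped[0].upper()
    return one if one in _KNOWN_ELEMENTS else stripped[0].upper()


def _parse_atom_line(line: str, lineno: int, dialect: str) -> Atom:
    if len(line) < 54:
        raise ParseError(f"line {lineno}: ATOM record too short")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # some generators leave serials blank; keep reading
    name = line[12:16].strip()
    altloc = line[16].strip()
    residue_name = line[17:21].strip()
    chain = line[21].strip()
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise ParseError(
            f"line {lineno}: malformed residue number {line[22:26]!r}"
        ) from exc
    icode = line[26].strip() if len(line) > 26 else ""
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(
            f"line {lineno}: malformed coordinate field in {line.rstrip()!r}"
        ) from exc
    if dialect == "pdbqt":
        element_field = line[77:79] if len(line) > 77 else ""
    else:
        element_field = line[76:78] if len(line) > 76 else ""
    element = _element_from_fields(name, element_field, dialect)
    if not element:
        raise ParseError(f"line {lineno}: cannot determine element for {name!r}")
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=np.array([x, y, z]),
        altloc=altloc,
        icode=icode,
    )


def _filter_altloc(atoms: list[Atom], path: str) -> list[Atom]:
    kept = [a for a in atoms if a.altloc in ("", "A")]
    if len(kept) != len(atoms):
        warnings.warn(
            f"{path}: dropped {len(atoms) - len(kept)} alternate-location "
            "atoms (kept altloc 'A'/blank)",
            stacklevel=3,
        )
    return kept


def _infer_dialect(path: str | Path) -> str:
    return "pdbqt" if str(path).lower().endswith(".pdbqt") else "pdb"


def read_receptor(
    path: str | Path, dialect: str | None = None
) -> ReceptorStructure:
    """Read a single-model receptor structure from PDB or PDBQT.

    Raises
    ------
    ParseError
        On malformed records (the message names the offending line) or if
        the file contains no atoms.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in ("pdb", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno, dialect))
            elif line.startswith("ENDMDL"):
                break  # receptors are single-model; ignore extra models
    atoms = _filter_altloc(atoms, str(path))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return ReceptorStructure(atoms=atoms)


def _parse_conect(lines: list[str], serial_to_index: dict[int, int]) -> list[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    for line in lines:
        fields = line.split()[1:]
        try:
            serials = [int(f) for f in fields]
        except ValueError:
            continue
        if not serials:
            continue
        first = serial_to_index.get(serials[0])
        if first is None:
            continue
        for s in serials[1:]:
            other = serial_to_index.get(s)
            if other is None or other == first:
                continue
            bonds.add((min(first, other), max(first, other)))
    return sorted(bonds)


def read_poses(path: str | Path, ligand_id: str | None = None) -> PoseSet:
    """Read a multi-MODEL pose file (PDB or PDBQT) into a :class:`PoseSet`.

    One pose per MODEL...ENDMDL block, in file order; a file without MODEL
    records is accepted as a single pose. Explicit CONECT records, if present,
    are attached to every pose (atom ordering is identical across poses).

    Raises
    ------
    ParseError
        If blocks have differing atom counts, no atoms are found, or a
        record is malformed.
    """
    dialect = _infer_dialect(path)
    blocks: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    saw_model = False
    conect_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = []
            elif line.startswith("ENDMDL"):
                if current:
                    blocks.append(current)
                in_model = False
                current = []
            elif line.startswith(("ATOM", "HETATM")):
                current.append(_parse_atom_line(line, lineno, dialect))
            elif line.startswith("CONECT"):
                conect_lines.append(line)
    if not saw_model and current:
        blocks.append(current)  # single unwrapped block counts as one pose
    elif saw_model and in_model and current:
        raise ParseError(f"{path}: unterminated MODEL block")
    if not blocks:
        raise ParseError(f"{path}: no poses found")
    counts = {len(b) for b in blocks}
    if len(counts) != 1:
        raise ParseError(
            f"{path}: MODEL blocks differ in atom count ({sorted(counts)})"
        )
    poses = []
    for k, atoms in enumerate(blocks, start=1):
        atoms = _filter_altloc(atoms, str(path))
        serial_to_index = {a.serial: i for i, a in enumerate(atoms)}
        bonds = _parse_conect(conect_lines, serial_to_index)
        poses.append(Pose(atoms=atoms, pose_index=k, bonds=bonds))
    if ligand_id is None:
        ligand_id = blocks[0][0].residue_name or Path(path).stem
    return PoseSet(ligand_id=ligand_id, poses=poses)


def _format_atom_line(atom: Atom, dialect: str, hetatm: bool = False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name = atom.name
    # PDB convention: 1-3 character names start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = atom.position
    line = (
        f"{record}{atom.serial:>5d} {padded}{atom.altloc or ' '}"
        f"{atom.residue_name:<4.4s}{atom.chain or 'A'}"
        f"{atom.residue_number:>4d}{atom.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
    )
    if dialect == "pdbqt":
        line += f"    {0.000:6.3f} {atom.element:<2s}"
    else:
        line += f"          {atom.element:>2s}"
    return line


def write_receptor(
    path: str | Path, structure: ReceptorStructure, dialect: str | None = None
) -> None:
    """Write a receptor to PDB/PDBQT (coordinates to 3 decimals)."""
    dialect = dialect or _infer_dialect(path)
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_atom_line(atom, dialect) + "\n")
        fh.write("END\n")


def write_poses(
    path: str | Path,
    pose_set: PoseSet,
    dialect: str | None = None,
    hetatm: bool = True,
) -> None:
    """Write a pose set as a multi-MODEL file, one block per pose."""
    dialect = dialect or _infer_dialect(path)
    with open(path, "w") as fh:
        for pose in pose_set.poses:
            fh.write(f"MODEL {pose.pose_index:>8d}\n")
            for atom in pose.atoms:
                fh.write(_format_atom_line(atom, dialect, hetatm=hetatm) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
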
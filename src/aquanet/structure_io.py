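"""Reading structures and trajectory frames into a uniform atom model.

Static structures are parsed with Bio.PDB; trajectory frames are read through
MDAnalysis and snapshotted into the same :class:`Structure` container so that
every downstream stage (alignment, network construction, clustering) sees one
in-memory model regardless of source.

Waters are identified by residue name against a configurable set; alternate
locations are collapsed to the highest-occupancy conformer (ties keep the
first encountered), and only the first MODEL of a multi-model file is used
for static input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_WATER_NAMES",
    "Atom",
    "Structure",
    "ActiveRegion",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "SelectionError",
    "read_structure",
    "read_frames",
    "select_region",
    "write_pdb",
    "write_multi_model_pdb",
]

#: Residue names recognised as water unless the caller overrides the set.
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SPC", "T3P", "SOL"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(Exception):
    """Base class for structure I/O failures."""


class FormatError(StructureError):
    """The file could not be parsed in the expected format."""


class EmptyStructureError(StructureError):
    """The file parsed but contained no atoms."""


class SelectionError(StructureError):
    """An atom selection expression matched nothing or is malformed."""


@dataclass
class Atom:
    """One atom of a structure or frame; coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_water: bool = False
    is_hydrogen: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, residue number, insertion code) — the residue identity used everywhere."""
        return (self.chain, self.residue_number, self.icode)

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coords - other.coords))


@dataclass
class Structure:
    """An ordered collection of atoms from one model or one trajectory frame."""

    id: str
    atoms: list[Atom]
    source: str = "static"  # "static" | "frame"
    frame_index: int | None = None

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError(f"structure {self.id}: atom serials are not unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def has_hydrogens(self) -> bool:
        """True when at least one water hydrogen is present."""
        return any(a.is_water and a.is_hydrogen for a in self.atoms)

    @property
    def water_oxygens(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water and not a.is_hydrogen and a.element == "O"]

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_water]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial} in structure {self.id}")

    def water_hydrogens_of(self, oxygen: Atom) -> list[Atom]:
        """Hydrogens belonging to the same water residue as *oxygen*."""
        key = oxygen.residue_key
        return [a for a in self.atoms
                if a.is_water and a.is_hydrogen and a.residue_key == key
                and a.residue_name == oxygen.residue_name]

    def residue_sequence(self) -> tuple[list[tuple[str, int, str]], str]:
        """Protein residues in atom order and their one-letter sequence (nonstandard → X)."""
        keys: list[tuple[str, int, str]] = []
        letters: list[str] = []
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.is_water:
                continue
            k = a.residue_key
            if k not in seen:
                seen.add(k)
                keys.append(k)
                letters.append(_THREE_TO_ONE.get(a.residue_name.upper(), "X"))
        return keys, "".join(letters)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with every atom mapped through x → R·x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_atoms = [replace(a, coords=rotation @ a.coords + translation) for a in self.atoms]
        return Structure(self.id, new_atoms, source=self.source, frame_index=self.frame_index)


@dataclass
class ActiveRegion:
    """A sphere restricting network construction.

    ``center_mode`` is ``"com"`` (center of mass of the selection, unweighted
    mean of coordinates) or ``"atom"`` (position of the first selected atom).
    Membership uses the closed ball: distance ≤ radius.
    """

    selection: str
    radius: float = 9.0
    center_mode: str = "com"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("active-region radius must be > 0")
        if self.center_mode not in ("com", "atom"):
            raise ValueError("center_mode must be 'com' or 'atom'")

    def resolve_center(self, structure: Structure) -> np.ndarray:
        selected = select_atoms(structure, self.selection)
        if self.center_mode == "atom":
            return selected[0].coords.copy()
        return np.mean([a.coords for a in selected], axis=0)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

def select_atoms(structure: Structure, expression: str) -> list[Atom]:
    """Resolve a selection expression to atoms.

    Clauses are joined with ``and``; each clause is one of
    ``protein``, ``water``, ``chain <id>``, ``resid <n>[-<m>]``,
    ``resname <name>[,<name>...]``, ``name <name>[,<name>...]``,
    ``serial <n>[-<m>]``.
    """
    clauses = [c.strip() for c in expression.split(" and ")]
    atoms = list(structure.atoms)
    for clause in clauses:
        parts = clause.split()
        if not parts:
            raise SelectionError(f"empty clause in selection {expression!r}")
        kw = parts[0].lower()
        if kw == "protein" and len(parts) == 1:
            atoms = [a for a in atoms if not a.is_water]
        elif kw == "water" and len(parts) == 1:
            atoms = [a for a in atoms if a.is_water]
        elif kw == "chain" and len(parts) == 2:
            atoms = [a for a in atoms if a.chain == parts[1]]
        elif kw in ("resid", "serial") and len(parts) == 2:
            lo, _, hi = parts[1].partition("-")
            try:
                lo_i = int(lo)
                hi_i = int(hi) if hi else lo_i
            except ValueError as exc:
                raise SelectionError(f"bad range in clause {clause!r}") from exc
            attr = "residue_number" if kw == "resid" else "serial"
            atoms = [a for a in atoms if lo_i <= getattr(a, attr) <= hi_i]
        elif kw in ("name", "resname") and len(parts) == 2:
            wanted = {w.strip().upper() for w in parts[1].split(",")}
            attr = "name" if kw == "name" else "residue_name"
            atoms = [a for a in atoms if getattr(a, attr).upper() in wanted]
        else:
            raise SelectionError(f"unrecognised selection clause {clause!r}")
    if not atoms:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return atoms


def select_region(structure: Structure, region: ActiveRegion) -> Structure:
    """Sub-structure of atoms inside the region sphere.

    Atoms that define the center (the region's selection) are always kept, so
    the operation is idempotent.  Water residues are kept or dropped as whole
    residues based on their oxygen position; protein atoms individually.
    """
    selected = select_atoms(structure, region.selection)
    selected_serials = {a.serial for a in selected}
    center = region.resolve_center(structure)

    water_keep: set[tuple[str, int, str]] = set()
    for a in structure.atoms:
        if a.is_water and not a.is_hydrogen and a.element == "O":
            if np.linalg.norm(a.coords - center) <= region.radius:
                water_keep.add(a.residue_key)

    kept: list[Atom] = []
    for a in structure.atoms:
        if a.serial in selected_serials:
            kept.append(a)
        elif a.is_water:
            if a.residue_key in water_keep:
                kept.append(a)
        elif np.linalg.norm(a.coords - center) <= region.radius:
            kept.append(a)
    return Structure(structure.id, kept, source=structure.source,
                     frame_index=structure.frame_index)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _element_from_name(name: str, residue_name: str, water_names: frozenset[str]) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if residue_name.upper() in water_names:
        return "H" if stripped[0].upper() in ("H", "D") else "O"
    return stripped[0].upper()


def read_structure(path: str | Path,
                   water_residue_names: Iterable[str] = DEFAULT_WATER_NAMES) -> Structure:
    """Read one PDB file into a :class:`Structure`.

    The first MODEL is used when several are present.  Alternate locations are
    reduced to the highest-occupancy conformer.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if path.exists() and path.stat().st_size == 0:
        raise EmptyStructureError(f"{path}: no atoms found")
    water_names = frozenset(n.upper() for n in water_residue_names)
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise FormatError(f"{path}: not parseable as PDB ({exc})") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no atoms found")
    model = models[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip().upper()
            het, resnum, icode = residue.get_id()
            is_water = resname in water_names
            for bio_atom in residue:
                # DisorderedAtom: Biopython's selected child is the highest-
                # occupancy altloc (ties keep the first encountered).
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                element = (bio_atom.element or "").strip().upper()
                if not element:
                    element = _element_from_name(bio_atom.get_name(), resname, water_names)
                occ = bio_atom.get_occupancy()
                atoms.append(Atom(
                    serial=int(bio_atom.get_serial_number()),
                    name=bio_atom.get_name(),
                    element=element,
                    residue_name=resname,
                    residue_number=int(resnum),
                    chain=chain.id.strip() or "A",
                    coords=np.asarray(bio_atom.get_coord(), dtype=float),
                    occupancy=1.0 if occ is None else float(occ),
                    is_water=is_water,
                    is_hydrogen=element in ("H", "D"),
                    icode=icode.strip(),
                ))
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms found")
    # duplicate serials can occur in sloppy files; renumber only if needed
    if len({a.serial for a in atoms}) != len(atoms):
        for i, a in enumerate(atoms):
            a.serial = i + 1
    return Structure(path.stem, atoms, source="static")


def read_frames(topology: str | Path,
                trajectory: str | Path,
                stride: int = 1,
                water_residue_names: Iterable[str] = DEFAULT_WATER_NAMES,
                ) -> Iterator[Structure]:
    """Yield one :class:`Structure` per selected trajectory frame.

    The trajectory must already be unwrapped and aligned to the common frame.
    Any format MDAnalysis can pair with the topology is accepted; coordinates
    are copied out of the reader so frames never alias each other.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be >= 1")
    water_names = frozenset(n.upper() for n in water_residue_names)
    try:
        universe = mda.Universe(str(topology), str(trajectory))
    except Exception as exc:
        raise FormatError(
            f"could not pair topology {topology} with trajectory {trajectory}: {exc}") from exc

    ag = universe.atoms
    try:
        elements = [str(e).upper() for e in ag.elements]
    except Exception:
        elements = [_element_from_name(n, rn, water_names)
                    for n, rn in zip(ag.names, ag.resnames)]
    try:
        occupancies = np.asarray(ag.occupancies, dtype=float)
    except Exception:
        occupancies = np.ones(len(ag))
    try:
        icodes = [str(i).strip() for i in ag.icodes]
    except Exception:
        icodes = [""] * len(ag)
    try:
        chains = [str(c).strip() or "A" for c in ag.chainIDs]
    except Exception:
        chains = [str(s)[:1] or "A" for s in ag.segids]

    resnames = [str(r).strip().upper() for r in ag.resnames]
    names = [str(n) for n in ag.names]
    resids = [int(r) for r in ag.resids]
    serials = list(range(1, len(ag) + 1))

    label = Path(str(trajectory)).stem
    for ts in universe.trajectory[::stride]:
        pos = np.array(ts.positions, dtype=float, copy=True)
        atoms = [Atom(serial=serials[i], name=names[i], element=elements[i],
                      residue_name=resnames[i], residue_number=resids[i],
                      chain=chains[i], coords=pos[i], occupancy=float(occupancies[i]),
                      is_water=resnames[i] in water_names,
                      is_hydrogen=elements[i] in ("H", "D"), icode=icodes[i])
                 for i in range(len(ag))]
        yield Structure(f"{label}", atoms, source="frame", frame_index=int(ts.frame))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _pdb_atom_line(a: Atom) -> str:
    record = "HETATM" if a.is_water else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    return (f"{record}{a.serial:>5d} {name:<4.4s} {a.residue_name:<3.3s} "
            f"{a.chain:>1.1s}{a.residue_number:>4d}{a.icode or ' ':>1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    lines = [_pdb_atom_line(a) for a in structure.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multi_model_pdb(structures: Sequence[Structure], path: str | Path) -> None:
    """Write frames as a multi-model PDB (usable as a toy trajectory)."""
    lines: list[str] = []
    for i, s in enumerate(structures, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.extend(_pdb_atom_line(a) for a in s.atoms)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
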
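"""Molecular data model, XYZ/PDB I/O, and geometric primitives.

The central container is :class:`Structure`, an ordered list of atoms with
Cartesian coordinates in Å and optional per-atom partial charges in units of
the elementary charge *e* (Mulliken-style charges when they come from an
electronic-structure engine).  Geometry helpers implement the axis-aligned
bounding-box volume used as the "geometric volume" of a host molecule, the
minimum intermolecular distance, and rigid-body transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "BoundingBox",
    "ParseError",
    "InputError",
    "read_structure",
    "write_xyz",
    "read_charge_file",
    "bounding_box",
    "bounding_box_volume",
    "min_intermolecular_distance",
    "transform",
]

#: Elements the model is routinely used with; extensions cover common
#: heteroatoms so PDB files with e.g. phosphorus still parse.
CORE_ELEMENTS = {"H", "C", "N", "O", "S"}
EXTENDED_ELEMENTS = CORE_ELEMENTS | {"P", "F", "Cl", "Br", "I", "B", "Si", "Se"}


class ParseError(ValueError):
    """A structure file violated its format; the message names the line."""


class InputError(ValueError):
    """Inconsistent or invalid input data (counts, charges, matrices)."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position (Å), optional partial charge (e)."""

    element: str
    position: np.ndarray
    charge: Optional[float] = None

    def __post_init__(self) -> None:
        el = self.element.capitalize() if len(self.element) > 1 else self.element.upper()
        object.__setattr__(self, "element", el)
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise InputError(f"atom position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise InputError("atom position components must be finite")
        object.__setattr__(self, "position", pos)
        if el not in EXTENDED_ELEMENTS:
            raise InputError(f"unsupported element symbol {el!r}")


@dataclass
class Structure:
    """An ordered set of atoms with a role tag (host or analyte).

    Atom order is significant and preserved across I/O round-trips; charges
    are all-or-none (either every atom carries one or none does).
    """

    atoms: list[Atom]
    role: Optional[str] = None  # "host" | "analyte" | None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise InputError("a structure needs at least one atom")
        n_charged = sum(a.charge is not None for a in self.atoms)
        if n_charged not in (0, len(self.atoms)):
            raise InputError("charges must be present on all atoms or none")
        if self.role not in (None, "host", "analyte"):
            raise InputError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms])

    @property
    def has_charges(self) -> bool:
        return self.atoms[0].charge is not None

    @property
    def charges(self) -> np.ndarray:
        """Per-atom partial charges (e); raises if absent."""
        if not self.has_charges:
            raise InputError(f"structure {self.name!r} carries no charges")
        return np.array([a.charge for a in self.atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self), 3):
            raise InputError("replacement coordinates have wrong shape")
        atoms = [replace(a, position=p) for a, p in zip(self.atoms, positions)]
        return Structure(atoms=atoms, role=self.role, name=self.name)

    def with_charges(self, charges: Sequence[float]) -> "Structure":
        charges = list(charges)
        if len(charges) != len(self):
            raise InputError(
                f"{len(charges)} charges for {len(self)} atoms"
            )
        atoms = [replace(a, charge=float(q)) for a, q in zip(self.atoms, charges)]
        return Structure(atoms=atoms, role=self.role, name=self.name)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box spanned by coordinate extrema, in the input frame."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if np.any(hi < lo):
            raise InputError("max_corner must dominate min_corner componentwise")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def volume(self) -> float:
        return float(np.prod(self.max_corner - self.min_corner))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_xyz(text: str, path: str) -> tuple[list[str], np.ndarray, Optional[list[float]]]:
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected atom count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: {n} atoms declared but only {len(lines) - 2} records")
    elements: list[str] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    for i, line in enumerate(lines[2 : n + 2], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {i}: need 'El x y z [q]'")
        elements.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
            if len(parts) >= 5:
                charges.append(float(parts[4]))
        except ValueError:
            raise ParseError(f"{path}, line {i}: non-numeric field") from None
    if charges and len(charges) != n:
        raise ParseError(f"{path}: charge column present on some lines but not all")
    return elements, np.array(coords), (charges or None)


def _parse_pdb(path: Path) -> tuple[list[str], np.ndarray]:
    # Biopython handles models/altlocs; we take the first model, coordinates only.
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("mol", str(path))
    model = next(structure.get_models())
    elements, coords = [], []
    for atom in model.get_atoms():
        el = atom.element.strip().capitalize() or atom.get_name()[0]
        elements.append(el)
        coords.append(atom.coord.astype(float))
    if not elements:
        raise ParseError(f"{path}: no ATOM/HETATM records in first model")
    return elements, np.array(coords)


def read_charge_file(path: str | Path) -> list[float]:
    """Read a charge sidecar: one value per line (e), order-matched to atoms."""
    values: list[float] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise ParseError(f"{path}, line {i}: non-numeric charge") from None
    return values


def read_structure(
    path: str | Path,
    format: Optional[str] = None,
    charges: Optional[str | Path] = None,
    role: Optional[str] = None,
    name: Optional[str] = None,
) -> Structure:
    """Read a molecule from an XYZ or PDB file.

    XYZ dialect: standard count/comment header then ``El x y z`` records; an
    optional 4th numeric column per atom carries the partial charge in e.
    A separate sidecar file (``charges=``) attaches charges positionally and
    overrides any in-file column.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if format == "xyz":
        elements, coords, inline_q = _parse_xyz(path.read_text(), str(path))
    elif format == "pdb":
        elements, coords = _parse_pdb(path)
        inline_q = None
    else:
        raise InputError(f"unknown format {format!r}")

    q: Optional[list[float]] = inline_q
    if charges is not None:
        q = read_charge_file(charges)
    if q is not None and len(q) != len(elements):
        raise InputError(
            f"{len(q)} charge entries for {len(elements)} atoms in {path}"
        )
    atoms = [
        Atom(el, xyz, None if q is None else q[i])
        for i, (el, xyz) in enumerate(zip(elements, coords))
    ]
    return Structure(atoms=atoms, role=role, name=name if name is not None else path.stem)


def write_xyz(s: Structure, path: str | Path, comment: str = "") -> None:
    """Write XYZ with 6-decimal coordinates; charge column emitted if present."""
    lines = [str(len(s)), comment.replace("\n", " ")]
    for a in s.atoms:
        rec = f"{a.element} {a.position[0]:.6f} {a.position[1]:.6f} {a.position[2]:.6f}"
        if a.charge is not None:
            rec += f" {a.charge:.6f}"
        lines.append(rec)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def bounding_box(s: Structure) -> BoundingBox:
    pos = s.positions
    return BoundingBox(pos.min(axis=0), pos.max(axis=0))


def bounding_box_volume(s: Structure) -> float:
    """Geometric volume (Å³): product of coordinate extents along x, y, z.

    The box is axis-aligned in the input coordinate frame and includes all
    atoms (hydrogens too).  A single atom yields 0.
    """
    return bounding_box(s).volume


def min_intermolecular_distance(
    a: Structure, b: Structure
) -> tuple[float, tuple[int, int]]:
    """Minimum cross-pair Euclidean distance (Å) and the realizing atom pair.

    Ties are broken by the lowest ``(a_index, b_index)`` pair.
    """
    from scipy.spatial.distance import cdist

    d = cdist(a.positions, b.positions)
    i, j = np.unravel_index(np.argmin(d), d.shape)  # argmin is first in C order
    return float(d[i, j]), (int(i), int(j))


def _check_rotation(rotation: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise InputError("rotation must be a 3x3 matrix")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise InputError("rotation must be orthonormal")
    if not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=1e-6):
        raise InputError("rotation must be proper (det = +1)")
    return r


def transform(
    s: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Apply a rigid transform ``x -> R x + t``; distances are preserved."""
    r = _check_rotation(rotation)
    t = np.asarray(translation, dtype=float).reshape(3)
    return s.with_positions(s.positions @ r.T + t)
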
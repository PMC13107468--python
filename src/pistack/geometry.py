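"""Molecular geometries, the slip-stack axis convention, and scan grids.

The convention used throughout the package: the fixed monomer lies in the
xy-plane with the long molecular axis along x and the short in-plane axis
along y.  A dimer arrangement is an exact translated copy of the fixed
monomer displaced by (dx, dy, dz) with dz > 0, i.e. the mobile monomer
floats above the fixed one at a constant inter-planar distance.

All coordinates handled here are in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Molecule",
    "DimerArrangement",
    "ScanGrid",
    "GeometryError",
    "PlanarityError",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "parse_xyz",
    "canonical_orient",
    "build_dimer",
    "make_grid",
]

PLANARITY_TOL = 1e-3  # Angstrom; absorbs file rounding only

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


class GeometryError(ValueError):
    """Invalid molecular geometry or dimer construction parameters."""


class PlanarityError(GeometryError):
    """Molecule is not planar within tolerance."""

    def __init__(self, max_dev: float):
        self.max_dev = max_dev
        super().__init__(
            f"molecule is not planar: max out-of-plane deviation "
            f"{max_dev:.4e} A exceeds tolerance {PLANARITY_TOL:g} A"
        )


class XYZParseError(ValueError):
    """Malformed XYZ file."""


@dataclass(frozen=True)
class Molecule:
    """A closed-shell molecule: element symbols plus Cartesian coordinates (A)."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (natom, 3), Angstrom
    charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape != (len(self.elements), 3):
            raise GeometryError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if len(self.elements) < 1:
            raise GeometryError("molecule must contain at least one atom")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates contain non-finite values")
        for el in self.elements:
            if el not in ATOMIC_NUMBERS:
                raise GeometryError(f"unknown element symbol {el!r}")
        if self.spin_multiplicity != 1:
            raise GeometryError("only closed-shell (singlet) molecules are supported")
        object.__setattr__(self, "coords", coords)

    @property
    def natom(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[e] for e in self.elements], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def formula(self) -> str:
        from collections import Counter

        counts = Counter(self.elements)
        parts = []
        for el in sorted(counts, key=lambda e: (e != "C", e != "H", e)):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def translated(self, shift) -> "Molecule":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def max_out_of_plane(self) -> float:
        """Max |z| coordinate; meaningful after canonical orientation."""
        return float(np.abs(self.coords[:, 2]).max())

    def is_planar(self, tol: float = PLANARITY_TOL) -> bool:
        return self.max_out_of_plane() < tol


@dataclass(frozen=True)
class DimerArrangement:
    """Fixed monomer in the xy-plane plus a translated mobile copy."""

    fixed: Molecule
    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if not self.dz > 0:
            raise GeometryError(f"dz must be positive, got {self.dz}")

    @property
    def mobile(self) -> Molecule:
        return self.fixed.translated((self.dx, self.dy, self.dz))

    @property
    def shift(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


@dataclass(frozen=True)
class ScanGrid:
    """1D displacement grid: shift `axis` from start to stop in steps (A)."""

    axis: str  # "x", "y" or "x_at_fixed_y"
    start: float
    stop: float
    step: float
    dz: float = 3.4
    fixed_dy: float | None = None

    def __post_init__(self):
        if self.axis not in ("x", "y", "x_at_fixed_y"):
            raise GeometryError(f"unknown scan axis {self.axis!r}")
        if not self.step > 0:
            raise GeometryError("step must be positive")
        if self.start > self.stop:
            raise GeometryError("start must not exceed stop")
        if self.axis == "x_at_fixed_y" and self.fixed_dy is None:
            raise GeometryError("axis 'x_at_fixed_y' requires fixed_dy")
        if self.axis in ("x", "y") and self.fixed_dy is not None:
            raise GeometryError(f"fixed_dy is only valid with axis 'x_at_fixed_y'")

    @property
    def points(self) -> np.ndarray:
        n = int(math.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


def parse_xyz(text: str, charge: int = 0) -> Molecule:
    """Parse standard XYZ content (count line, comment line, atom lines)."""
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ content")
    try:
        natom = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise XYZParseError(f"malformed atom-count line 1: {lines[0]!r}") from exc
    if len(lines) < natom + 2:
        raise XYZParseError(
            f"header declares {natom} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines are present"
        )
    elements, coords = [], []
    for i in range(natom):
        line = lines[2 + i]
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"malformed coordinate line {3 + i}: {line!r}")
        el = parts[0].capitalize()
        if el not in ATOMIC_NUMBERS:
            raise GeometryError(f"unknown element symbol {parts[0]!r} on line {3 + i}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise XYZParseError(f"malformed coordinate line {3 + i}: {line!r}") from exc
        elements.append(el)
        coords.append(xyz)
    return Molecule(tuple(elements), np.array(coords), charge=charge)


def read_xyz(path, charge: int = 0) -> Molecule:
    """Read a molecule from an XYZ file (coordinates in Angstrom)."""
    with open(path) as fh:
        return parse_xyz(fh.read(), charge=charge)


def write_xyz(mol: Molecule, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{mol.natom}\n{comment}\n")
        for el, (x, y, z) in zip(mol.elements, mol.coords):
            fh.write(f"{el} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal axes from the gyration tensor, refined to the convention:
    columns ordered by decreasing coordinate extent, signs made deterministic."""
    natom = coords.shape[0]
    gyr = coords.T @ coords / natom
    _, vecs = np.linalg.eigh(gyr)  # ascending eigenvalues
    axes = vecs[:, ::-1].copy()

    # Extent-based ordering (the long axis is a geometric statement).
    extents = [
        coords @ axes[:, k] for k in range(3)
    ]
    spans = [p.max() - p.min() for p in extents]
    order = np.argsort(spans)[::-1]
    axes = axes[:, order]

    # Near-degenerate in-plane directions (e.g. sixfold symmetry): rotate the
    # in-plane frame so the atom farthest from the centroid lies on +x.
    proj = coords @ axes
    span_x = proj[:, 0].max() - proj[:, 0].min()
    span_y = proj[:, 1].max() - proj[:, 1].min()
    if abs(span_x - span_y) < 1e-6 and natom > 2:
        r2 = proj[:, 0] ** 2 + proj[:, 1] ** 2
        imax = int(np.argmax(np.round(r2, 8)))
        phi = math.atan2(proj[imax, 1], proj[imax, 0])
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        axes = axes @ rot

    proj = coords @ axes
    # Sign convention: first atom with |component| > tol gets a positive value.
    for k in range(2):
        for v in proj[:, k]:
            if abs(v) > 1e-8:
                if v < 0:
                    axes[:, k] = -axes[:, k]
                break
    # Right-handed frame.
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return axes


def canonical_orient(mol: Molecule, require_planar: bool = True) -> Molecule:
    """Translate the centroid to the origin and rotate into the axis convention.

    The molecular plane is mapped onto the xy-plane, the direction of largest
    coordinate extent onto x and the second largest onto y.  Deterministic
    sign fixing: along x and y the first atom with a nonzero component is
    made positive.  Raises :class:`PlanarityError` for non-planar input when
    ``require_planar`` is set.
    """
    coords = mol.coords - mol.coords.mean(axis=0)
    if mol.natom == 1:
        return replace(mol, coords=coords)
    axes = _principal_axes(coords)
    new = coords @ axes
    out = replace(mol, coords=new)
    if require_planar and not out.is_planar():
        raise PlanarityError(out.max_out_of_plane())
    return out


def build_dimer(mol: Molecule, dx: float, dy: float, dz: float) -> DimerArrangement:
    """Slip-stacked dimer: translated copy of `mol` shifted by (dx, dy, dz)."""
    return DimerArrangement(fixed=mol, dx=float(dx), dy=float(dy), dz=float(dz))


def make_grid(mol: Molecule, grid: ScanGrid) -> list[DimerArrangement]:
    """All dimer arrangements of a scan grid, in increasing shift order."""
    out = []
    for t in grid.points:
        if grid.axis == "x":
            out.append(build_dimer(mol, t, 0.0, grid.dz))
        elif grid.axis == "y":
            out.append(build_dimer(mol, 0.0, t, grid.dz))
        else:
            out.append(build_dimer(mol, t, grid.fixed_dy, grid.dz))
    return out
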
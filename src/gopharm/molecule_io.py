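"""Molecule container, file I/O and canonical orientation.

Molecules are plain containers of per-atom coordinates (Å), van der Waals
radii (Å) and partial charges (elementary charge units).  Before
superposition both query and target are put in a canonical frame: centroid
at the origin, longest principal axis along X, shortest along Z.

SDF (V2000) records are read and written through RDKit.  TRIPOS MOL2 is
handled by a minimal internal reader/writer because RDKit cannot write
MOL2 and its reader insists on sanitizable valences, which bond-less
synthetic fixtures do not have.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np

logger = logging.getLogger("gopharm")

__all__ = [
    "Atom",
    "Molecule",
    "BoundingBox",
    "load_radius_table",
    "read_molecules",
    "write_molecules",
    "assign_vdw_radii",
    "canonical_orientation",
    "bounding_box",
]


class Atom(NamedTuple):
    """Read-only view of one atom of a :class:`Molecule`."""

    position: np.ndarray
    vdw_radius: float
    partial_charge: float
    element: str


@dataclass
class Molecule:
    """A rigid molecule: coordinates, vdW radii and partial charges.

    Parameters
    ----------
    id : str
        Identifier, e.g. a DrugBank accession like ``"DB09114"``.
    coords : (n, 3) ndarray
        Atom positions in Å.
    radii : (n,) ndarray
        van der Waals radii sigma_i in Å, strictly positive.
    charges : (n,) ndarray
        Partial charges in elementary charge units.
    elements : list of str
        Element symbols, one per atom.
    """

    id: str
    coords: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        n = self.coords.shape[0]
        if n < 1 or self.coords.shape[1] != 3:
            raise ValueError(f"molecule {self.id!r}: need an (n, 3) coordinate array, n >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id!r}: non-finite coordinates")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError(f"molecule {self.id!r}: radii must be positive, one per atom")
        if self.charges.shape != (n,):
            raise ValueError(f"molecule {self.id!r}: need one charge per atom")
        if not self.elements:
            self.elements = ["C"] * n
        if len(self.elements) != n:
            raise ValueError(f"molecule {self.id!r}: need one element symbol per atom")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(self.coords[i].copy(), float(self.radii[i]), float(self.charges[i]), self.elements[i])
            for i in range(self.n_atoms)
        ]

    def copy(self, **changes) -> "Molecule":
        base = dict(
            id=self.id,
            coords=self.coords.copy(),
            radii=self.radii.copy(),
            charges=self.charges.copy(),
            elements=list(self.elements),
        )
        base.update(changes)
        return Molecule(**base)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box over atom centers."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner


# ---------------------------------------------------------------------------
# vdW radius table

def load_radius_table(path: str | Path | None = None) -> dict[str, float]:
    """Load an element -> radius (Å) table from TSV.

    Defaults to the Bondi set shipped with the package.
    """
    if path is None:
        text = resources.files("gopharm").joinpath("data/bondi_radii.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, value = line.split("\t")[:2]
        table[element] = float(value)
    return table


def assign_vdw_radii(mol: Molecule, table: dict[str, float] | None = None) -> Molecule:
    """Set every atom's sigma_i from its element symbol, overwriting existing radii."""
    if table is None:
        table = load_radius_table()
    missing = sorted({el for el in mol.elements if el not in table})
    if missing:
        raise KeyError(f"no vdW radius for element(s): {', '.join(missing)}")
    radii = np.array([table[el] for el in mol.elements], dtype=float)
    return mol.copy(radii=radii)


# ---------------------------------------------------------------------------
# SDF via RDKit

_CHARGE_PROP = "PARTIAL_CHARGES"


def _read_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    default_radii = load_radius_table()
    out: list[Molecule] = []
    for idx, rd in enumerate(supplier):
        if rd is None:
            raise ValueError(f"{path}: record {idx} is not a valid SDF (V2000) entry")
        if rd.GetNumAtoms() == 0:
            raise ValueError(f"{path}: record {idx} has zero atoms")
        conf = rd.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in rd.GetAtoms()]
        if rd.HasProp(_CHARGE_PROP):
            charges = np.array([float(t) for t in rd.GetProp(_CHARGE_PROP).split()])
            if charges.size != rd.GetNumAtoms():
                raise ValueError(f"{path}: record {idx}: {_CHARGE_PROP} length mismatch")
        else:
            charges = np.zeros(rd.GetNumAtoms())
            logger.warning("%s: record %d has no partial charges; using zeros", path, idx)
        radii = np.array([default_radii.get(el, 1.70) for el in elements])
        name = rd.GetProp("_Name") if rd.HasProp("_Name") else f"{path.stem}_{idx}"
        out.append(Molecule(id=name or f"{path.stem}_{idx}", coords=coords, radii=radii,
                            charges=charges, elements=elements))
    return out


def _write_sdf(mols: list[Molecule], path: Path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in mols:
            rd = Chem.RWMol()
            for el in mol.elements:
                rd.AddAtom(Chem.Atom(el))
            conf = Chem.Conformer(mol.n_atoms)
            for i, (x, y, z) in enumerate(mol.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            rd.AddConformer(conf)
            rd.SetProp("_Name", mol.id)
            rd.SetProp(_CHARGE_PROP, " ".join(f"{q:.6f}" for q in mol.charges))
            rd.UpdatePropertyCache(strict=False)
            writer.write(rd)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# TRIPOS MOL2 (minimal, ATOM records with the charge column)

def _read_mol2(path: Path) -> list[Molecule]:
    default_radii = load_radius_table()
    text = path.read_text()
    blocks = [b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    if not blocks:
        raise ValueError(f"{path}: no @<TRIPOS>MOLECULE records found")
    out: list[Molecule] = []
    for idx, block in enumerate(blocks):
        lines = block.splitlines()
        name = lines[1].strip() if len(lines) > 1 else f"{path.stem}_{idx}"
        coords, charges, elements = [], [], []
        in_atoms = False
        has_charges = False
        for line in lines:
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                in_atoms = stripped == "@<TRIPOS>ATOM"
                continue
            if not in_atoms or not stripped:
                continue
            fields = stripped.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: record {idx}: malformed ATOM line {stripped!r}")
            coords.append([float(fields[2]), float(fields[3]), float(fields[4])])
            element = fields[5].split(".")[0]
            elements.append(element)
            if len(fields) >= 9:
                charges.append(float(fields[8]))
                has_charges = True
            else:
                charges.append(0.0)
        if not coords:
            raise ValueError(f"{path}: record {idx} ({name!r}) has zero atoms")
        if not has_charges:
            logger.warning("%s: record %d has no charge column; using zeros", path, idx)
        radii = np.array([default_radii.get(el, 1.70) for el in elements])
        out.append(Molecule(id=name or f"{path.stem}_{idx}", coords=np.array(coords),
                            radii=radii, charges=np.array(charges), elements=elements))
    return out


def _write_mol2(mols: list[Molecule], path: Path) -> None:
    parts: list[str] = []
    for mol in mols:
        parts.append("@<TRIPOS>MOLECULE")
        parts.append(mol.id)
        parts.append(f"{mol.n_atoms} 0 0 0 0")
        parts.append("SMALL")
        parts.append("USER_CHARGES")
        parts.append("@<TRIPOS>ATOM")
        for i in range(mol.n_atoms):
            x, y, z = mol.coords[i]
            el = mol.elements[i]
            parts.append(
                f"{i + 1:>7d} {el + str(i + 1):<5s} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
                f"{el:<5s} 1 MOL {mol.charges[i]:>10.6f}"
            )
        parts.append("@<TRIPOS>BOND")
    Path(path).write_text("\n".join(parts) + "\n")


def read_molecules(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read all molecules from an SDF or MOL2 file.

    Hydrogens are retained; partial charges are taken from the file when
    present (MOL2 charge column, SDF ``PARTIAL_CHARGES`` property) and
    default to zero with a warning otherwise.  vdW radii are assigned from
    the bundled Bondi table by element.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unsupported format {fmt!r}; expected 'sdf' or 'mol2'")


def write_molecules(mols: list[Molecule] | Molecule, path: str | Path,
                    format: str | None = None) -> None:
    """Write molecules to SDF (via RDKit) or MOL2 (TRIPOS ATOM records)."""
    if isinstance(mols, Molecule):
        mols = [mols]
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        _write_sdf(mols, path)
    elif fmt == "mol2":
        _write_mol2(mols, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; expected 'sdf' or 'mol2'")


# ---------------------------------------------------------------------------
# Canonical starting orientation

def canonical_orientation(mol: Molecule, return_transform: bool = False):
    """Center the molecule and align principal axes: longest on X, shortest on Z.

    The rotation is proper (det = +1).  Axis signs for X and Y follow the
    largest-|projection| atom convention (that atom ends up with a positive
    component); Z is then X x Y so the frame stays right-handed.  Applying
    the function twice is a no-op up to 1e-9 Å for non-degenerate clouds.
    """
    centroid = mol.coords.mean(axis=0)
    centered = mol.coords - centroid
    cov = centered.T @ centered / mol.n_atoms
    eigvals, eigvecs = np.linalg.eigh(cov)        # ascending
    order = np.argsort(eigvals)[::-1]             # largest variance first -> X
    axes = eigvecs[:, order].T                    # rows: new X, Y, Z in old frame

    if eigvals[order[0]] < 1e-18:                 # all atoms coincident
        logger.warning("molecule %r: degenerate geometry; centering only", mol.id)
        out = mol.copy(coords=centered)
        return (out, np.eye(3), centroid) if return_transform else out

    for a in range(2):                            # sign convention for X, Y
        proj = centered @ axes[a]
        if proj[np.argmax(np.abs(proj))] < 0:
            axes[a] = -axes[a]
    axes[2] = np.cross(axes[0], axes[1])          # right-handed, det = +1

    out = mol.copy(coords=centered @ axes.T)
    return (out, axes, centroid) if return_transform else out


def bounding_box(mol: Molecule) -> BoundingBox:
    """Axis-aligned bounding box over atom centers (no radius padding)."""
    return BoundingBox(mol.coords.min(axis=0).copy(), mol.coords.max(axis=0).copy())
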
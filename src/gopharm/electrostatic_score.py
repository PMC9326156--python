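"""Grid electrostatic-potential overlap and electrostatic Tanimoto.

The potential phi of a molecule is evaluated on a regular grid; the
masked product integral

    E_AB ~= h^3 * sum_{ijk} phi^A phi^B Theta^A Theta^B

measures how alike two potential fields are outside the molecular
envelopes (the binary mask Theta zeroes nodes inside any atom's vdW
sphere).  Similarity is the Tanimoto ratio Tc_E = E_AB / (E_AA + E_BB -
E_AB), which lives in [-1/3, 1]: 1 for identical fields, 0 for disjoint
ones, and -1/3 when the fields are exact opposites (E_AB = -E_AA).

The physical potential solves a Poisson problem; here phi comes from a
pluggable potential model, by default a uniform-dielectric Coulomb sum
phi(r) = sum_a q_a / (4 pi eps |r - r_a|).  The similarity machinery is
independent of how phi is produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ElectroParams
from .molecule_io import Molecule, bounding_box
from .pose_transform import Pose, SearchDomain, transform_coords

__all__ = [
    "GridSpec",
    "PotentialGrid",
    "ElectroCache",
    "potential_grid",
    "overlap_energy",
    "electrostatic_tanimoto",
    "ElectrostaticOverlay",
    "write_dx",
]

_MIN_DIST = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (Å), spacing h (Å), dims (nx, ny, nz)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 nodes per axis")

    @classmethod
    def covering(cls, mol: Molecule, params: ElectroParams) -> "GridSpec":
        """Grid covering the molecule's bounding box plus the margin."""
        box = bounding_box(mol)
        lo = box.min_corner - params.margin
        hi = box.max_corner + params.margin
        dims = tuple(int(np.ceil((hi[a] - lo[a]) / params.h)) + 1 for a in range(3))
        return cls(origin=lo, spacing=params.h, dims=dims)

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny*nz, 3), C order."""
        ax = [self.origin[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


@dataclass(frozen=True)
class PotentialGrid:
    """Potential field phi and binary mask Theta on a grid (flattened, C order)."""

    spec: GridSpec
    phi: np.ndarray
    mask: np.ndarray


def _coulomb_phi(coords: np.ndarray, charges: np.ndarray, nodes: np.ndarray,
                 epsilon: float) -> np.ndarray:
    d = np.linalg.norm(nodes[:, None, :] - coords[None, :, :], axis=-1)
    return (charges / np.maximum(d, _MIN_DIST)).sum(axis=1) / (4.0 * np.pi * epsilon)


def _phi_and_mask(coords, radii, charges, nodes, params: ElectroParams):
    d = np.linalg.norm(nodes[:, None, :] - coords[None, :, :], axis=-1)
    mask = np.all(d > radii[None, :], axis=1)
    if callable(params.potential_model):
        phi = params.potential_model(coords, charges, nodes)
    else:
        phi = (charges / np.maximum(d, _MIN_DIST)).sum(axis=1) / (4.0 * np.pi * params.epsilon)
    return phi, mask


def potential_grid(mol: Molecule, spec: GridSpec | None = None,
                   params: ElectroParams | None = None) -> PotentialGrid:
    """Evaluate the molecule's potential and vdW mask on a grid.

    Theta = 0 at nodes with |r - r_a| <= sigma_a for any atom a, 1
    elsewhere; phi from the configured potential model (default Coulomb).
    """
    import logging

    params = params or ElectroParams()
    spec = spec or GridSpec.covering(mol, params)
    if np.all(mol.charges == 0.0):
        logging.getLogger("gopharm").warning(
            "molecule %r has all-zero charges; potential is identically zero", mol.id)
    phi, mask = _phi_and_mask(mol.coords, mol.radii, mol.charges, spec.nodes(), params)
    return PotentialGrid(spec=spec, phi=phi, mask=mask)


def overlap_energy(query_grid: PotentialGrid, target_mol: Molecule,
                   pose: Pose | None = None,
                   params: ElectroParams | None = None) -> float:
    """Masked potential-product integral E_AB = h^3 sum phi^A phi^B Theta^A Theta^B.

    The target's phi and Theta are evaluated exactly on the query's grid
    nodes from the pose-transformed atom positions, so no interpolation
    error enters and the operation is symmetric in the two roles.
    """
    params = params or ElectroParams()
    coords = target_mol.coords if pose is None else transform_coords(
        target_mol.coords, pose.as_array())
    live = query_grid.mask
    if not np.any(live):
        return 0.0
    nodes = query_grid.spec.nodes()[live]
    phi_b, mask_b = _phi_and_mask(coords, target_mol.radii, target_mol.charges,
                                  nodes, params)
    h3 = query_grid.spec.spacing**3
    return float(h3 * np.sum(query_grid.phi[live] * phi_b * mask_b))


@dataclass(frozen=True)
class ElectroCache:
    """Per-molecule self grid and self energy E_AA (rigid-motion invariant)."""

    grid: PotentialGrid
    self_energy: float

    @classmethod
    def build(cls, mol: Molecule, params: ElectroParams | None = None) -> "ElectroCache":
        params = params or ElectroParams()
        grid = potential_grid(mol, None, params)
        h3 = grid.spec.spacing**3
        e_self = float(h3 * np.sum((grid.phi * grid.mask) ** 2))
        return cls(grid=grid, self_energy=e_self)


def electrostatic_tanimoto(A: Molecule, B: Molecule, pose: Pose | None = None,
                           cache: tuple[ElectroCache, ElectroCache] | None = None,
                           params: ElectroParams | None = None) -> float:
    """Electrostatic Tanimoto Tc_E = E_AB / (E_AA + E_BB - E_AB), in [-1/3, 1].

    E_AB is taken on A's grid with B posed; the self terms come from each
    molecule's own grid (same spacing and margin) and are cached.
    """
    params = params or ElectroParams()
    if cache is None:
        cache = (ElectroCache.build(A, params), ElectroCache.build(B, params))
    ca, cb = cache
    e_ab = overlap_energy(ca.grid, B, pose, params)
    denom = ca.self_energy + cb.self_energy - e_ab
    if denom <= 0.0:
        raise FloatingPointError("electrostatic Tanimoto denominator <= 0")
    return e_ab / denom


class ElectrostaticOverlay:
    """Electrostatic-similarity objective for one query-target pair.

    Callable on a 6-vector pose, returning the cost -Tc_E.  The query's
    masked nodes and phi are precomputed; each evaluation re-evaluates the
    target's potential and mask at those nodes (atoms x nodes work).
    """

    def __init__(self, query: Molecule, target: Molecule,
                 params: ElectroParams | None = None):
        params = params or ElectroParams()
        self.params = params
        self.query = query
        self.target = target
        self.cache = (ElectroCache.build(query, params), ElectroCache.build(target, params))
        grid = self.cache[0].grid
        live = grid.mask
        self._nodes = grid.spec.nodes()[live]
        self._phi_a = grid.phi[live]
        self._h3 = grid.spec.spacing**3
        self._self_sum = self.cache[0].self_energy + self.cache[1].self_energy
        self.domain = SearchDomain.for_pair(query, target)

    def tanimoto(self, x) -> float:
        coords = transform_coords(self.target.coords, np.asarray(x, dtype=float))
        phi_b, mask_b = _phi_and_mask(coords, self.target.radii, self.target.charges,
                                      self._nodes, self.params)
        e_ab = float(self._h3 * np.sum(self._phi_a * phi_b * mask_b))
        denom = self._self_sum - e_ab
        if denom <= 0.0:
            raise FloatingPointError("electrostatic Tanimoto denominator <= 0")
        return e_ab / denom

    def __call__(self, x) -> float:
        return -self.tanimoto(x)


def write_dx(grid: PotentialGrid, path) -> None:
    """Dump phi (mask applied) as an OpenDX scalar field for visual inspection."""
    nx, ny, nz = grid.spec.dims
    ox, oy, oz = grid.spec.origin
    h = grid.spec.spacing
    values = grid.phi * grid.mask
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6e} {oy:.6e} {oz:.6e}",
        f"delta {h:.6e} 0 0",
        f"delta 0 {h:.6e} 0",
        f"delta 0 0 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    for start in range(0, values.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in values[start:start + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
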
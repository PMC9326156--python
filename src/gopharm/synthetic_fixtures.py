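"""Synthetic molecule generator for offline, download-free testing.

Generates random bond-less "molecules" (coordinate clouds with vdW radii
and net-neutral partial charges) and known-pose transformed copies, so
superposition, scoring and recovery can all be exercised against ground
truth.  The generator is pure: a spec plus a seed fully determines the
output.  No chemical realism (topology, valence, aromaticity) is
attempted or needed by the scoring machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule_io import Molecule
from .pose_transform import Pose, apply_pose

__all__ = ["FixtureSpec", "random_molecule", "transformed_copy"]

_ELEMENTS = ("H", "C", "N", "O", "S")


@dataclass(frozen=True)
class FixtureSpec:
    """What a random fixture looks like.

    Defaults emulate a drug-like small molecule: ~20 heavy+light atoms in
    an 8 Å cloud, vdW radii spanning the H..S Bondi range, per-atom
    partial charges of a few tenths of an elementary charge, net-neutral.
    """

    n_atoms: int = 20
    radius_range: tuple[float, float] = (1.2, 1.8)
    charge_range: tuple[float, float] = (-0.4, 0.4)
    spatial_extent: float = 8.0
    neutralize: bool = True
    min_anisotropy: float = 1.5   # reject clouds with lambda1/lambda3 below this

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError("n_atoms >= 1 required")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be a positive interval")
        if self.spatial_extent <= 0:
            raise ValueError("spatial_extent must be positive")


def _anisotropy(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    eig = np.linalg.eigvalsh(centered.T @ centered / coords.shape[0])
    return float(eig[-1] / max(eig[0], 1e-12))


def random_molecule(spec: FixtureSpec | None = None,
                    rng: np.random.Generator | int | None = None,
                    mol_id: str = "synthetic") -> Molecule:
    """Random molecule: uniform atoms in a cube, uniform radii and charges.

    Charges are shifted to zero net charge (so electrostatic similarity
    exercises sign structure rather than monopole dominance).  Point-
    symmetric layouts are avoided by rejecting clouds whose principal-
    moment ratio lambda1/lambda3 falls below ``min_anisotropy``, which
    keeps pose-recovery optima unique.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(rng)
    half = spec.spatial_extent / 2.0
    for _ in range(1000):
        coords = rng.uniform(-half, half, size=(spec.n_atoms, 3))
        if spec.n_atoms < 4 or _anisotropy(coords) >= spec.min_anisotropy:
            break
    radii = rng.uniform(*spec.radius_range, size=spec.n_atoms)
    charges = rng.uniform(*spec.charge_range, size=spec.n_atoms)
    if spec.neutralize and spec.n_atoms > 0:
        charges = charges - charges.mean()
    elements = [str(rng.choice(_ELEMENTS)) for _ in range(spec.n_atoms)]
    return Molecule(id=mol_id, coords=coords, radii=radii, charges=charges,
                    elements=elements)


def transformed_copy(mol: Molecule, pose: Pose, noise_sigma: float = 0.0,
                     rng: np.random.Generator | int | None = None,
                     mol_id: str | None = None) -> tuple[Molecule, Pose]:
    """Pose-transformed copy of a molecule, plus the generating pose.

    Optional isotropic Gaussian jitter of ``noise_sigma`` Å is added to
    the transformed coordinates.  The returned pose is the ground truth
    for recovery assertions.
    """
    rng = np.random.default_rng(rng)
    moved = apply_pose(mol, pose)
    if noise_sigma > 0.0:
        moved = moved.copy(coords=moved.coords + rng.normal(0.0, noise_sigma,
                                                            size=moved.coords.shape))
    if mol_id is not None:
        moved = moved.copy(id=mol_id)
    elif moved.id == mol.id:
        moved = moved.copy(id=f"{mol.id}_posed")
    return moved, pose
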
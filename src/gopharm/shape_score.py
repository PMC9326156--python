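"""Weighted Gaussian shape overlap and shape Tanimoto.

Each atom is a soft Gaussian sphere g_i(r) = p * exp(-alpha_i |r - r_i|^2)
with alpha_i = (3 p sqrt(pi) / (4 sigma_i^3))^(2/3), chosen so the Gaussian
integrates to the hard-sphere volume at the conventional softness p.  The
molecular overlap is a first-order weighted sum over atom pairs,

    V_AB = sum_{i in A, j in B} w_i w_j v_ij,

where the weights w_i = v_i / (v_i + k * sum_{j != i} v_ij) (k = 0.8665)
correct the first-order sum for intra-molecular overlap, WEGA style.  The
weights depend only on intra-molecular distances, so they are rigid-motion
invariant and computed once per molecule.  Similarity is reported as the
shape Tanimoto Tc_S = V_AB / (V_AA + V_BB - V_AB) in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ShapeParams
from .molecule_io import Molecule
from .pose_transform import Pose, SearchDomain, transform_coords

__all__ = [
    "ShapeCache",
    "gaussian_alpha",
    "pair_overlap",
    "atom_weights",
    "overlap_volume",
    "shape_tanimoto",
    "ShapeOverlay",
]


def gaussian_alpha(radii: np.ndarray, p: float) -> np.ndarray:
    """Gaussian decay coefficients alpha_i for vdW radii sigma_i."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("vdW radii must be positive")
    return (3.0 * p * np.sqrt(np.pi) / (4.0 * radii**3)) ** (2.0 / 3.0)


def _pair_matrix(coords_a, radii_a, coords_b, radii_b, params: ShapeParams) -> np.ndarray:
    """All pairwise Gaussian overlap volumes v_ij, shape (nA, nB)."""
    ai = gaussian_alpha(radii_a, params.p)[:, None]
    aj = gaussian_alpha(radii_b, params.p)[None, :]
    d2 = np.sum((coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1)
    v = params.p**2 * (np.pi / (ai + aj)) ** 1.5 * np.exp(-ai * aj / (ai + aj) * d2)
    cut = params.cutoff_factor * (np.asarray(radii_a)[:, None] + np.asarray(radii_b)[None, :])
    v[d2 > cut * cut] = 0.0
    return v


def pair_overlap(atom_i, atom_j, params: ShapeParams | None = None) -> float:
    """Closed-form overlap integral of two atomic Gaussians, Å³.

    v_ij = p^2 (pi / (alpha_i + alpha_j))^(3/2)
           * exp(-alpha_i alpha_j d^2 / (alpha_i + alpha_j)).

    Symmetric in (i, j) and strictly decreasing in the center distance d.
    """
    params = params or ShapeParams()
    ai = float(gaussian_alpha(np.array([atom_i.vdw_radius]), params.p)[0])
    aj = float(gaussian_alpha(np.array([atom_j.vdw_radius]), params.p)[0])
    d2 = float(np.sum((np.asarray(atom_i.position) - np.asarray(atom_j.position)) ** 2))
    return params.p**2 * (np.pi / (ai + aj)) ** 1.5 * np.exp(-ai * aj / (ai + aj) * d2)


def atom_weights(mol: Molecule, params: ShapeParams | None = None) -> np.ndarray:
    """WEGA atom weights w_i = v_i / (v_i + k * sum_{j != i} v_ij), in (0, 1].

    v_i is the hard-sphere volume 4 pi sigma_i^3 / 3 and the neighbor sum
    runs over the other atoms of the same molecule.
    """
    params = params or ShapeParams()
    v_sphere = 4.0 * np.pi * mol.radii**3 / 3.0
    v = _pair_matrix(mol.coords, mol.radii, mol.coords, mol.radii, params)
    np.fill_diagonal(v, 0.0)
    return v_sphere / (v_sphere + params.k * v.sum(axis=1))


def overlap_volume(A: Molecule, B: Molecule, wA: np.ndarray, wB: np.ndarray,
                   params: ShapeParams | None = None) -> float:
    """Weighted first-order Gaussian overlap volume V_AB, Å³."""
    params = params or ShapeParams()
    v = _pair_matrix(A.coords, A.radii, B.coords, B.radii, params)
    return float(wA @ v @ wB)


@dataclass(frozen=True)
class ShapeCache:
    """Per-molecule shape terms: weights w_i and self-overlap V_AA."""

    weights: np.ndarray
    self_overlap: float

    @classmethod
    def build(cls, mol: Molecule, params: ShapeParams | None = None) -> "ShapeCache":
        params = params or ShapeParams()
        w = atom_weights(mol, params)
        return cls(weights=w, self_overlap=overlap_volume(mol, mol, w, w, params))


def shape_tanimoto(A: Molecule, B: Molecule, pose: Pose | None = None,
                   cache: tuple[ShapeCache, ShapeCache] | None = None,
                   params: ShapeParams | None = None) -> float:
    """Shape Tanimoto Tc_S = V_AB / (V_AA + V_BB - V_AB) with B posed.

    A stays fixed in the query frame; ``pose`` is applied to B before
    scoring.  Weights and self-overlaps are rigid-motion invariant and may
    be passed in via ``cache`` (cache_A, cache_B).
    """
    params = params or ShapeParams()
    if cache is None:
        cache = (ShapeCache.build(A, params), ShapeCache.build(B, params))
    ca, cb = cache
    posed = B if pose is None else B.copy(coords=transform_coords(B.coords, pose.as_array()))
    v_ab = overlap_volume(A, posed, ca.weights, cb.weights, params)
    denom = ca.self_overlap + cb.self_overlap - v_ab
    if denom <= 0.0:
        raise FloatingPointError("shape Tanimoto denominator <= 0: inconsistent inputs")
    return v_ab / denom


class ShapeOverlay:
    """Shape-similarity objective for one query-target pair.

    Callable on a 6-vector pose; returns the cost -Tc_S (the optimizer
    minimizes).  ``tanimoto(x)`` returns the similarity itself.  Pairwise
    Gaussian prefactors are precomputed once; each evaluation costs one
    rigid transform plus an (nA x nB) exponential.
    """

    def __init__(self, query: Molecule, target: Molecule,
                 params: ShapeParams | None = None):
        params = params or ShapeParams()
        self.params = params
        self.query = query
        self.target = target
        self.cache = (ShapeCache.build(query, params), ShapeCache.build(target, params))
        wA, wB = self.cache[0].weights, self.cache[1].weights
        ai = gaussian_alpha(query.radii, params.p)[:, None]
        aj = gaussian_alpha(target.radii, params.p)[None, :]
        self._decay = ai * aj / (ai + aj)
        self._pref = (wA[:, None] * wB[None, :]
                      * params.p**2 * (np.pi / (ai + aj)) ** 1.5)
        self._qcoords = query.coords
        self._tcoords = target.coords
        self._self_sum = self.cache[0].self_overlap + self.cache[1].self_overlap
        self.domain = SearchDomain.for_pair(query, target)

    def tanimoto(self, x) -> float:
        moved = transform_coords(self._tcoords, np.asarray(x, dtype=float))
        d2 = np.sum((self._qcoords[:, None, :] - moved[None, :, :]) ** 2, axis=-1)
        v_ab = float(np.sum(self._pref * np.exp(-self._decay * d2)))
        return v_ab / (self._self_sum - v_ab)

    def __call__(self, x) -> float:
        return -self.tanimoto(x)
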
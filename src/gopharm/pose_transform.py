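"""Six-variable rigid-pose parametrization and the search domain.

A pose is (alpha, theta, phi, dx, dy, dz): rotation by alpha about a unit
axis given in semisphere spherical coordinates (theta, phi), followed by a
translation.  Restricting phi to [0, pi/2] keeps the axis on the closed
upper hemisphere so every axis has a unique code (antiparallel axes
describe the same rotation set once alpha spans [0, 2pi]).

The projection operator keeps optimizer candidates inside the domain:
circular (double-modulus) wrapping for alpha and theta, clamping for phi
and the translations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule_io import Molecule, bounding_box

__all__ = [
    "Pose",
    "SearchDomain",
    "axis_from_angles",
    "rotation_matrix",
    "apply_pose",
    "translation_bounds",
    "project",
]

TWO_PI = 2.0 * np.pi
HALF_PI = 0.5 * np.pi


@dataclass(frozen=True)
class Pose:
    """Rigid placement of the target: rotate about the origin, then translate."""

    alpha: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.theta, self.phi, self.dx, self.dy, self.dz])

    @classmethod
    def from_array(cls, x) -> "Pose":
        a = np.asarray(x, dtype=float).ravel()
        if a.shape != (6,):
            raise ValueError("a pose has exactly 6 variables")
        return cls(*a)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


@dataclass(frozen=True)
class SearchDomain:
    """Per-variable bounds Omega = prod_j [L_j, U_j], order (alpha, theta, phi, dx, dy, dz)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != (6,) or self.upper.shape != (6,):
            raise ValueError("search domain needs 6 lower and 6 upper bounds")
        if np.any(self.lower >= self.upper):
            raise ValueError("search domain requires L_j < U_j for every variable")

    @classmethod
    def from_translation_bounds(cls, max_xyz) -> "SearchDomain":
        mx, my, mz = (float(v) for v in max_xyz)
        return cls(
            lower=np.array([0.0, 0.0, 0.0, -mx, -my, -mz]),
            upper=np.array([TWO_PI, TWO_PI, HALF_PI, mx, my, mz]),
        )

    @classmethod
    def for_pair(cls, query: Molecule, target: Molecule) -> "SearchDomain":
        return cls.from_translation_bounds(translation_bounds(query, target))

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Uniform poses in Omega, shape (n, 6)."""
        return rng.uniform(self.lower, self.upper, size=(n, 6))


def axis_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit rotation axis from semisphere angles.

    x = cos(theta) sin(phi), y = sin(theta) sin(phi), z = cos(phi); with
    phi in [0, pi/2] the axis lies on the closed upper hemisphere.
    """
    s = np.sin(phi)
    return np.array([np.cos(theta) * s, np.sin(theta) * s, np.cos(phi)])


def rotation_matrix(axis: np.ndarray, alpha: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle alpha."""
    x, y, z = axis
    c, s = np.cos(alpha), np.sin(alpha)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def apply_pose(mol: Molecule, pose: Pose) -> Molecule:
    """Rotate about the origin by (alpha, axis(theta, phi)), then translate.

    Radii and charges are untouched; the molecule is assumed pre-centered
    (query frame) so the rotation center is the shared origin.
    """
    R = rotation_matrix(axis_from_angles(pose.theta, pose.phi), pose.alpha)
    return mol.copy(coords=mol.coords @ R.T + pose.translation)


def transform_coords(coords: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Array-level apply_pose for objective hot loops; x = 6-vector."""
    R = rotation_matrix(axis_from_angles(x[1], x[2]), x[0])
    return coords @ R.T + x[3:6]


def translation_bounds(query: Molecule, target: Molecule) -> tuple[float, float, float]:
    """Per-axis translation limits (max_X, max_Y, max_Z).

    Half the summed box extents per axis: the largest displacement at
    which the two bounding boxes can still touch.  Axes where both boxes
    are flat get a 1 Å floor so the domain stays non-degenerate.
    """
    eq = bounding_box(query).extent
    et = bounding_box(target).extent
    bounds = (eq + et) / 2.0
    bounds[bounds == 0.0] = 1.0
    return (float(bounds[0]), float(bounds[1]), float(bounds[2]))


def project_array(x: np.ndarray, dom: SearchDomain) -> np.ndarray:
    """Projection onto Omega for a (6,) or (n, 6) array (see :func:`project`)."""
    x = np.array(x, dtype=float, copy=True)
    u = dom.upper
    # circular limits for alpha and theta: mod(mod(x, U) + U, U) -> [0, U)
    x[..., :2] = np.mod(np.mod(x[..., :2], u[:2]) + u[:2], u[:2])
    x[..., 2:] = np.clip(x[..., 2:], dom.lower[2:], u[2:])
    return x


def project(pose: Pose, dom: SearchDomain) -> Pose:
    """Project a pose into the search domain.

    alpha and theta wrap circularly into [0, 2pi) via the double modulus
    (so negatives come back positive); phi and the translations clamp to
    their bounds.  Idempotent.
    """
    return Pose.from_array(project_array(pose.as_array(), dom))
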
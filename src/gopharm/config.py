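"""Parameter containers and YAML config loading.

Defaults follow the published operating point of the optimizer
(N=10, M_iter=1000, n_m=20, delta=1e-4) and field-standard scoring
parameters (Gaussian softness p=2.7, weight constant k=0.8665).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["ShapeParams", "ElectroParams", "GOPharmConfig", "load_config"]


@dataclass(frozen=True)
class ShapeParams:
    """Gaussian shape-overlap parameters.

    p : dimensionless softness of the atomic Gaussians (2.7, the value at
        which a Gaussian sphere reproduces the hard-sphere volume).
    k : weight constant of the first-order overlap correction (0.8665).
    cutoff_factor : pair terms with d > cutoff_factor * (sigma_i + sigma_j)
        are dropped; at 4.5 the discarded Gaussian tail is < 1e-12 of the
        d=0 value, so this is purely a speed optimization.
    """

    p: float = 2.7
    k: float = 0.8665
    cutoff_factor: float = 4.5

    def __post_init__(self):
        if self.p <= 0 or self.k <= 0:
            raise ValueError("ShapeParams: p and k must be positive")


@dataclass(frozen=True)
class ElectroParams:
    """Grid electrostatics parameters.

    h : grid spacing in Å (0.5 by default).
    margin : grid padding beyond the molecule bounding box, Å.
    epsilon : uniform relative dielectric for the Coulomb potential model.
    potential_model : "coulomb" or a callable plugin
        ``f(coords, charges, nodes) -> phi`` replacing the default
        uniform-dielectric Coulomb sum.
    """

    h: float = 0.5
    margin: float = 5.0
    epsilon: float = 4.0
    potential_model: object = "coulomb"

    def __post_init__(self):
        if self.h <= 0 or self.margin <= 0 or self.epsilon <= 0:
            raise ValueError("ElectroParams: h, margin and epsilon must be positive")


@dataclass(frozen=True)
class GOPharmConfig:
    """Optimizer settings.

    N : population size (>= 2; >= 8 for the two-layer driver).
    M_iter : iterations per optimizer run.
    delta : convergence-test tolerance freeing the rotation-axis variables.
    n_m : polynomial-mutation distribution index.
    window : convergence-test lookback in iterations (fixed at 5).
    literal_exponent : audit switch replacing the bounded polynomial-mutation
        exponent (r^(1/(n_m+1)) - 1) with the literal r^(1/(n_m+1) - 1) reading.
    """

    N: int = 10
    M_iter: int = 1000
    delta: float = 1.0e-4
    n_m: float = 20.0
    window: int = 5
    literal_exponent: bool = False

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("GOPharmConfig: N >= 2 required")
        if self.M_iter < 1 or self.delta <= 0 or self.n_m <= 0:
            raise ValueError("GOPharmConfig: M_iter >= 1, delta > 0, n_m > 0 required")


def load_config(path: str | Path):
    """Read a YAML file with optional ``optimizer``, ``shape``, ``electro`` sections.

    Returns (GOPharmConfig, ShapeParams, ElectroParams).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def build(cls, section):
        allowed = {f.name for f in fields(cls)}
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
        return cls(**section)

    return (
        build(GOPharmConfig, raw.get("optimizer", {})),
        build(ShapeParams, raw.get("shape", {})),
        build(ElectroParams, raw.get("electro", {})),
    )
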
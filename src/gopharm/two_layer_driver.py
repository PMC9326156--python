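"""Two-layer strategy: four exploratory runs seed one exploitation run.

Layer 1 executes four independent optimizer runs, each seeded with one
problem-knowledge starting pose: the identity, and half-turns about the
OX, OY and OZ axes.  Layer 2 runs once more with an initial population
built from the four first-layer optima, four axis-flipped variants of
them (theta - pi/2, pi/2 - phi, everything else redrawn), and random
fill.  Elitist seeding makes the final similarity at least the best
first-layer one; the added diversity is what rescues runs whose four
exploratory optima are all local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gopharm_optimizer import Individual, RunResult, run_gopharm
from .pose_transform import HALF_PI, Pose, SearchDomain, project

__all__ = ["TwoLayerResult", "starting_poses", "flip_axis", "run_two_layer"]

FIRST_LAYER_LABELS = ("SP", "OX", "OY", "OZ")


@dataclass(frozen=True)
class TwoLayerResult:
    """Four first-layer runs (SP, OX, OY, OZ) plus the final run."""

    first_layer: tuple[RunResult, RunResult, RunResult, RunResult]
    final: RunResult
    total_phase_evals: int

    @property
    def best(self) -> Individual:
        return self.final.best

    @property
    def best_similarity(self) -> float:
        return self.final.best.similarity


def starting_poses() -> tuple[Pose, Pose, Pose, Pose]:
    """The four problem-knowledge first-layer seeds.

    Identity, then pi rotations about OX, OY and OZ.  The identity's axis
    sits at the phi=0 pole (axis (0,0,1)) -- with alpha=0 any axis codes
    the identity; the pole is chosen for determinism.
    """
    return (
        Pose(),                                              # SP: identity
        Pose(alpha=np.pi, theta=0.0, phi=HALF_PI),           # OX half-turn
        Pose(alpha=np.pi, theta=HALF_PI, phi=HALF_PI),       # OY half-turn
        Pose(alpha=np.pi, theta=0.0, phi=0.0),               # OZ half-turn
    )


def flip_axis(ind: Individual, dom: SearchDomain, rng: np.random.Generator,
              objective=None) -> Individual:
    """Axis-flipped variant of a first-layer optimum.

    theta~ = theta - pi/2 (circularly projected), phi~ = pi/2 - phi (still
    on the upper semisphere); alpha and the translations are redrawn
    uniformly.  Evaluated on construction when an objective is supplied,
    else carries cost = nan until the caller evaluates it.
    """
    x = ind.pose.as_array()
    rand = dom.sample(rng, 1)[0]
    flipped = np.array([rand[0], x[1] - HALF_PI, HALF_PI - x[2],
                        rand[3], rand[4], rand[5]])
    pose = project(Pose.from_array(flipped), dom)
    cost = float(objective(pose.as_array())) if objective is not None else float("nan")
    return Individual(pose=pose, cost=cost)


def run_two_layer(objective, dom: SearchDomain, config,
                  rng: np.random.Generator | int | None = None) -> TwoLayerResult:
    """Full two-layer optimization of one query-target pair.

    The five optimizer runs draw from independent substreams spawned from
    the master generator, so the whole procedure is reproducible from one
    seed.  Requires config.N >= 8 so the four first-layer optima and their
    four flipped variants fit in the second-layer population.
    """
    if config.N < 8:
        raise ValueError("two-layer driver needs N >= 8 (4 optima + 4 flipped seeds)")
    rng = np.random.default_rng(rng)
    streams = rng.spawn(6)        # 4 first-layer runs, flip draws, final run

    first = tuple(
        run_gopharm(objective, dom, config, seeds=[pose], rng=streams[i])
        for i, pose in enumerate(starting_poses())
    )

    flip_rng = streams[4]
    optima = [r.best.pose for r in first]
    flipped = [flip_axis(r.best, dom, flip_rng, objective) for r in first]
    seeds = optima + [f.pose for f in flipped]

    final = run_gopharm(objective, dom, config, seeds=seeds, rng=streams[5])
    # flipped-seed construction evaluations belong to the second layer's init
    final = RunResult(best=final.best, history=final.history,
                      phase_evals=final.phase_evals,
                      init_evals=final.init_evals + len(flipped),
                      dup_evals=final.dup_evals,
                      axis_free_trace=final.axis_free_trace)

    total = sum(r.phase_evals for r in first) + final.phase_evals
    return TwoLayerResult(first_layer=first, final=final, total_phase_evals=total)
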
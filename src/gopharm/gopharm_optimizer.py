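"""Guided evolutionary optimizer over the 6-variable pose space.

A population of N poses is evolved for M_iter iterations, each iteration
applying three phases -- leader, collaborative and self-guiding -- every
one of which evaluates exactly one candidate per individual and accepts
it only on strict improvement (the optimizer minimizes a cost, here
-similarity).  Per-run objective evaluations inside the phases are
therefore 3 * N * M_iter exactly; initialization and duplicate
re-evaluations are accounted separately.

Domain knowledge enters twice.  Angular variables alpha and theta wrap
circularly under projection instead of clamping.  And the rotation-axis
variables (theta, phi) are frozen until a convergence test detects
stagnation of the best cost over a 5-iteration window: while a given axis
still yields progress the search exploits it by tuning only the rotation
angle and translation; once progress stalls the axis is released.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose_transform import Pose, SearchDomain, project_array

__all__ = [
    "Individual",
    "Population",
    "RunResult",
    "initialize_population",
    "convergence_test",
    "leader_phase",
    "collaborative_phase",
    "self_guiding_phase",
    "resolve_duplicates",
    "run_gopharm",
]

_AXIS = slice(1, 3)  # theta, phi positions in the 6-vector


@dataclass(frozen=True)
class Individual:
    """A pose plus its cached cost (the minimized objective value)."""

    pose: Pose
    cost: float

    @property
    def similarity(self) -> float:
        """Similarity recovered from the minimization convention cost = -Tc."""
        return -self.cost


@dataclass
class Population:
    """Matrix view of the population: X[i] is individual i's 6 variables."""

    X: np.ndarray           # (N, 6)
    costs: np.ndarray       # (N,)
    phase_evals: int = 0
    init_evals: int = 0
    dup_evals: int = 0

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.costs))

    @property
    def best(self) -> Individual:
        i = self.best_index
        return Individual(Pose.from_array(self.X[i]), float(self.costs[i]))


@dataclass(frozen=True)
class RunResult:
    """Outcome of one optimizer run."""

    best: Individual
    history: np.ndarray          # best cost after init and after each iteration
    phase_evals: int
    init_evals: int
    dup_evals: int = 0
    axis_free_trace: np.ndarray | None = None

    @property
    def best_similarity(self) -> float:
        return self.best.similarity


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    """Evaluate rows of X; uses objective.batch when provided."""
    batch = getattr(objective, "batch", None)
    if batch is not None:
        return np.asarray(batch(X), dtype=float)
    return np.array([objective(x) for x in X], dtype=float)


def initialize_population(dom: SearchDomain, N: int, seeds, rng: np.random.Generator,
                          objective) -> Population:
    """Seed poses verbatim plus uniform-random fill, all projected and evaluated."""
    seeds = list(seeds or [])
    if len(seeds) > N:
        raise ValueError(f"{len(seeds)} seed poses exceed population size N={N}")
    seeded = np.array([s.as_array() if isinstance(s, Pose) else np.asarray(s, dtype=float)
                       for s in seeds]).reshape(len(seeds), 6)
    X = np.vstack([seeded, dom.sample(rng, N - len(seeds))]) if len(seeds) < N else seeded
    X = project_array(X, dom)
    costs = _evaluate(objective, X)
    return Population(X=X, costs=costs, init_evals=N)


def convergence_test(history, k: int, delta: float) -> bool:
    """Release the rotation axis once the best cost stagnates.

    ``history`` holds the best cost after initialization (index 0) and
    after each completed iteration.  At iteration k the test compares the
    current best with the one recorded five iterations earlier (clamped
    to the initialization value for k=5, the first iteration at which the
    test can run).  Returns True -- axis variables free -- iff k >= 5 and
    the absolute difference is below delta.  Evaluated fresh every
    iteration, never latched.
    """
    if k < 5:
        return False
    cur = history[k - 1]
    prev = history[max(k - 6, 0)]
    return abs(cur - prev) < delta


def _polynomial_delta(r: np.ndarray, n_m: float, literal: bool) -> np.ndarray:
    """Bounded polynomial-mutation factor r^(1/(n_m+1)) (literal: r^(1/(n_m+1)-1))."""
    expo = 1.0 / (n_m + 1.0) - 1.0 if literal else 1.0 / (n_m + 1.0)
    return r**expo


def _accept(pop: Population, cand: np.ndarray, cand_costs: np.ndarray) -> None:
    better = cand_costs < pop.costs       # strict: ties keep the incumbent
    pop.X[better] = cand[better]
    pop.costs[better] = cand_costs[better]


def leader_phase(pop: Population, objective, dom: SearchDomain, axis_free: bool,
                 n_m: float, rng: np.random.Generator, literal_exponent: bool = False) -> Population:
    """Move every individual toward the population leader.

    The leader T is the current argmin; with a per-individual leading
    factor TF in {1, 2} and a per-variable polynomial-mutation reference
    point R around T, each candidate is

        X~_ij = X_ij + rt_ij * (T_j - TF * mean_j + (TF - 1) * R_ij).

    Axis variables are reverted to their incumbents unless the
    convergence test freed them; candidates are projected, evaluated (one
    phase evaluation per individual) and accepted on strict improvement.
    """
    N = pop.N
    T = pop.X[pop.best_index].copy()
    mean = pop.X.mean(axis=0)
    TF = rng.integers(1, 3, size=N).astype(float)[:, None]

    r1 = rng.uniform(size=(N, 6))
    r2 = rng.uniform(size=(N, 6))
    diff = T[None, :] - pop.X
    lower_branch = (diff < 0) | ((diff == 0) & (r2 < 0.5))
    step = _polynomial_delta(r1, n_m, literal_exponent)
    R = np.where(lower_branch,
                 T + (step - 1.0) * (T - dom.lower)[None, :],
                 T + (1.0 - step) * (dom.upper - T)[None, :])

    rt = rng.uniform(size=(N, 6))
    cand = pop.X + rt * (T[None, :] - TF * mean[None, :] + (TF - 1.0) * R)
    if not axis_free:
        cand[:, _AXIS] = pop.X[:, _AXIS]
    cand = project_array(cand, dom)
    cand_costs = _evaluate(objective, cand)
    pop.phase_evals += N
    _accept(pop, cand, cand_costs)
    return pop


def collaborative_phase(pop: Population, objective, dom: SearchDomain, axis_free: bool,
                        rng: np.random.Generator) -> Population:
    """Pairwise knowledge exchange.

    Each individual i picks a random partner i~ != i and moves toward it
    when the partner is better (away when worse, nowhere on a tie):

        X~_ij = X_ij + rl_ij * (X_i~j - X_ij) * sign(f_i - f_i~).
    """
    N = pop.N
    if N < 2:
        raise ValueError("collaborative phase needs N >= 2")
    partners = (np.arange(N) + rng.integers(1, N, size=N)) % N   # uniform over j != i
    sign = np.sign(pop.costs - pop.costs[partners])[:, None]
    rl = rng.uniform(size=(N, 6))
    cand = pop.X + rl * (pop.X[partners] - pop.X) * sign
    if not axis_free:
        cand[:, _AXIS] = pop.X[:, _AXIS]
    cand = project_array(cand, dom)
    cand_costs = _evaluate(objective, cand)
    pop.phase_evals += N
    _accept(pop, cand, cand_costs)
    return pop


def self_guiding_phase(pop: Population, objective, dom: SearchDomain, axis_free: bool,
                       n_m: float, rng: np.random.Generator,
                       literal_exponent: bool = False) -> Population:
    """Polynomial mutation of each individual around itself.

    With a fresh r3 per variable: for r3 <= 0.5 the variable moves toward
    its lower bound by ((2 r3)^(1/(n_m+1)) - 1) * (X - L); otherwise
    toward the upper bound by (1 - (2(1-r3))^(1/(n_m+1))) * (U - X).
    r3 = 0.5 leaves the variable unchanged.
    """
    N = pop.N
    r3 = rng.uniform(size=(N, 6))
    down = _polynomial_delta(2.0 * r3, n_m, literal_exponent) - 1.0
    up = 1.0 - _polynomial_delta(2.0 * (1.0 - r3), n_m, literal_exponent)
    cand = np.where(r3 <= 0.5,
                    pop.X + down * (pop.X - dom.lower[None, :]),
                    pop.X + up * (dom.upper[None, :] - pop.X))
    if not axis_free:
        cand[:, _AXIS] = pop.X[:, _AXIS]
    cand = project_array(cand, dom)
    cand_costs = _evaluate(objective, cand)
    pop.phase_evals += N
    _accept(pop, cand, cand_costs)
    return pop


def resolve_duplicates(pop: Population, dom: SearchDomain, rng: np.random.Generator,
                       objective=None, rel_tol: float = 1e-9,
                       axis_free: bool = True) -> Population:
    """Perturb duplicated individuals so the population stays diverse.

    Two individuals are duplicates when all six variables agree within
    ``rel_tol`` (relative to the variable range).  One of each duplicated
    pair receives a uniform perturbation of up to +/-1% of the range on a
    random nonempty subset of coordinates, is projected back into the
    domain, and re-evaluated (counted in dup_evals, not phase_evals).
    While the convergence test holds the rotation axis (``axis_free``
    False) the perturbable subset excludes theta and phi.
    """
    span = dom.span
    movable = np.ones(6, dtype=bool)
    if not axis_free:
        movable[_AXIS] = False
    for _ in range(100):                      # bounded; collisions are measure-zero
        tol = rel_tol * span
        dup_rows: list[int] = []
        seen: list[int] = []
        # scan best-first so the kept representative of a duplicate cluster is
        # its best member (keeps the best-cost history non-increasing)
        for i in np.argsort(pop.costs, kind="stable"):
            if any(np.all(np.abs(pop.X[i] - pop.X[j]) <= tol) for j in seen):
                dup_rows.append(int(i))
            else:
                seen.append(int(i))
        if not dup_rows:
            break
        for i in dup_rows:
            subset = (rng.uniform(size=6) < 0.5) & movable
            if not subset.any():
                choices = np.flatnonzero(movable)
                subset[rng.choice(choices)] = True
            pert = rng.uniform(-0.01, 0.01, size=6) * span
            pop.X[i] = pop.X[i] + np.where(subset, pert, 0.0)
        pop.X[dup_rows] = project_array(pop.X[dup_rows], dom)
        if objective is not None:
            pop.costs[dup_rows] = _evaluate(objective, pop.X[dup_rows])
            pop.dup_evals += len(dup_rows)
        else:
            pop.costs[dup_rows] = np.inf
    return pop


def run_gopharm(objective, dom: SearchDomain, config, seeds=None,
                rng: np.random.Generator | int | None = None,
                callback=None) -> RunResult:
    """One full optimizer run: initialization plus M_iter guided iterations.

    Each iteration: convergence test -> leader -> collaborative ->
    self-guiding -> duplicate resolution.  Returns the best individual,
    the (non-increasing) best-cost history, and the evaluation accounting
    (phase_evals = 3 * N * M_iter exactly).  ``callback(k, pop,
    axis_free)``, when given, is invoked after every iteration with the
    live population (for tracing and invariant auditing).
    """
    rng = np.random.default_rng(rng)
    pop = initialize_population(dom, config.N, seeds, rng, objective)
    history = [float(pop.costs.min())]
    axis_trace = np.zeros(config.M_iter, dtype=bool)

    for k in range(1, config.M_iter + 1):
        axis_free = convergence_test(history, k, config.delta)
        axis_trace[k - 1] = axis_free
        leader_phase(pop, objective, dom, axis_free, config.n_m, rng,
                     config.literal_exponent)
        collaborative_phase(pop, objective, dom, axis_free, rng)
        self_guiding_phase(pop, objective, dom, axis_free, config.n_m, rng,
                           config.literal_exponent)
        resolve_duplicates(pop, dom, rng, objective, axis_free=axis_free)
        history.append(float(pop.costs.min()))
        if callback is not None:
            callback(k, pop, axis_free)

    return RunResult(best=pop.best, history=np.array(history),
                     phase_evals=pop.phase_evals, init_evals=pop.init_evals,
                     dup_evals=pop.dup_evals, axis_free_trace=axis_trace)
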
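"""Guided optimizer: phases, convergence test, accounting, determinism."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from gopharm import GOPharmConfig, Pose, SearchDomain, convergence_test, run_gopharm
from gopharm.gopharm_optimizer import (
    Population,
    collaborative_phase,
    initialize_population,
    leader_phase,
    resolve_duplicates,
    self_guiding_phase,
)

UNIT_DOM = SearchDomain(lower=np.zeros(6), upper=np.ones(6))


class SumObjective:
    """cost = sum of variables; cheap and monotone for hand traces."""

    def __call__(self, x):
        return float(np.sum(x))

    def batch(self, X):
        return np.sum(X, axis=1)


class SphereObjective:
    """cost = |x - 1|^2 over the 6 pose variables."""

    def __call__(self, x):
        return float(np.sum((np.asarray(x) - 1.0) ** 2))

    def batch(self, X):
        return np.sum((X - 1.0) ** 2, axis=1)


class RecordingObjective(SumObjective):
    def __init__(self):
        self.seen = []

    def batch(self, X):
        self.seen.append(np.array(X, copy=True))
        return super().batch(X)


class ScriptedRng:
    """Replays a fixed list of arrays in call order; shapes are checked."""

    def __init__(self, script):
        self.script = list(script)

    def _pop(self, size):
        out = np.asarray(self.script.pop(0), dtype=float)
        want = (size,) if isinstance(size, int) else tuple(size or ())
        assert out.shape == want, f"script shape {out.shape} != requested {want}"
        return out

    def uniform(self, low=0.0, high=1.0, size=None):
        return low + (high - low) * self._pop(size)

    def integers(self, low, high=None, size=None):
        return self._pop(size).astype(int)


class TestInitialization:
    def test_seeds_present_verbatim_plus_random_fill(self, rng):
        seed_pose = Pose(alpha=0.25, theta=0.5, phi=0.25, dx=0.1, dy=0.2, dz=0.3)
        pop = initialize_population(UNIT_DOM, 10, [seed_pose], rng, SumObjective())
        assert pop.N == 10
        np.testing.assert_array_equal(pop.X[0], seed_pose.as_array())
        assert pop.init_evals == 10
        assert np.all(pop.X >= 0) and np.all(pop.X <= 1)

    def test_no_seeds_all_random_in_bounds(self, rng):
        pop = initialize_population(UNIT_DOM, 10, [], rng, SumObjective())
        assert pop.N == 10
        assert np.all((pop.X >= 0) & (pop.X <= 1))

    def test_deterministic_given_seed(self):
        a = initialize_population(UNIT_DOM, 10, [], np.random.default_rng(5),
                                  SumObjective())
        b = initialize_population(UNIT_DOM, 10, [], np.random.default_rng(5),
                                  SumObjective())
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.costs, b.costs)

    def test_too_many_seeds_rejected(self, rng):
        seeds = [Pose()] * 3
        with pytest.raises(ValueError):
            initialize_population(UNIT_DOM, 2, seeds, rng, SumObjective())


class TestConvergenceTest:
    def test_cannot_run_before_iteration_five(self):
        assert convergence_test([1.0, 0.9, 0.8], 3, 1e-4) is False

    def test_stagnant_history_frees_the_axis(self):
        history = [0.5] * 6
        assert convergence_test(history, 5, 1e-4) is True

    def test_large_improvement_keeps_the_axis(self):
        history = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        assert convergence_test(history, 5, 1e-4) is False

    def test_not_latched(self):
        # stagnation at k=5, renewed progress visible at k=7
        history = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.1]
        assert convergence_test(history, 5, 1e-4) is True
        assert convergence_test(history, 7, 1e-4) is False


class TestLeaderPhase:
    def test_scalar_trace_matches_direct_formula(self):
        """Two-individual hand trace of the reference point and update."""
        n_m = 20.0
        X = np.array([[0.6] * 6, [0.2] * 6])
        pop = Population(X=X.copy(), costs=np.array([3.6, 1.2]))  # leader: row 1
        r1, r2, rt = 0.5, 0.25, 0.5
        rng = ScriptedRng([
            np.array([2, 2]),            # TF per individual
            np.full((2, 6), r1),         # r1
            np.full((2, 6), r2),         # r2
            np.full((2, 6), rt),         # rt
        ])
        leader_phase(pop, SumObjective(), UNIT_DOM, axis_free=True, n_m=n_m, rng=rng)

        T, mean, L, U = 0.2, 0.4, 0.0, 1.0
        step = r1 ** (1.0 / (n_m + 1.0))
        # both rows hit the lower reference branch: row 0 has T - X < 0,
        # row 1 (the leader) has T - X = 0 with r2 < 0.5
        R = T + (step - 1.0) * (T - L)
        cand0 = 0.6 + rt * (T - 2.0 * mean + R)     # ~0.397: improves, accepted
        cand1 = 0.2 + rt * (T - 2.0 * mean + R)     # ~-0.003: wraps/clamps, worse
        assert cand0 > 0 and cand1 < 0
        wrapped1 = cand1 % 1.0                       # circular vars alpha, theta
        assert 2 * wrapped1 > 1.2                    # cost after projection is worse
        np.testing.assert_allclose(pop.X[0], np.full(6, cand0), atol=1e-12)
        np.testing.assert_array_equal(pop.X[1], X[1])  # rejected, incumbent kept
        assert pop.costs[0] == pytest.approx(6 * cand0, abs=1e-12)
        assert pop.phase_evals == 2

    def test_identical_population_with_tf_one_is_a_fixed_point(self):
        X = np.full((3, 6), 0.4)
        pop = Population(X=X.copy(), costs=np.full(3, 2.4))
        rng = ScriptedRng([
            np.ones(3),                  # TF = 1 for everyone
            np.random.default_rng(0).uniform(size=(3, 6)),   # r1 (unused with TF=1)
            np.random.default_rng(1).uniform(size=(3, 6)),   # r2
            np.random.default_rng(2).uniform(size=(3, 6)),   # rt
        ])
        leader_phase(pop, SumObjective(), UNIT_DOM, True, 20.0, rng)
        # T = mean = X -> zero step (up to round-off in the population mean)
        np.testing.assert_allclose(pop.X, X, atol=1e-12)

    def test_leader_is_argmin(self):
        costs = np.array([3.0, 1.0, 2.0])
        pop = Population(X=np.random.default_rng(0).uniform(size=(3, 6)),
                         costs=costs.copy())
        assert pop.best_index == 1

    def test_axis_variables_held_when_locked(self, rng):
        pop = initialize_population(UNIT_DOM, 10, [], rng, SumObjective())
        before = pop.X[:, 1:3].copy()
        leader_phase(pop, SumObjective(), UNIT_DOM, axis_free=False, n_m=20.0, rng=rng)
        np.testing.assert_array_equal(pop.X[:, 1:3], before)


class TestCollaborativePhase:
    def test_equal_costs_give_zero_step(self, rng):
        X = np.random.default_rng(3).uniform(size=(4, 6))
        pop = Population(X=X.copy(), costs=np.zeros(4))
        collaborative_phase(pop, SumObjective(), UNIT_DOM, True, rng)
        np.testing.assert_array_equal(pop.X, X)  # sign(0) = 0 everywhere
        assert pop.phase_evals == 4

    def test_worse_individual_moves_toward_partner(self):
        rl = 0.5
        X = np.array([[0.8] * 6, [0.2] * 6])
        pop = Population(X=X.copy(), costs=np.array([4.8, 1.2]))
        rng = ScriptedRng([
            np.array([1, 1]),            # partner offsets -> partners (1, 0)
            np.full((2, 6), rl),         # rl
        ])
        collaborative_phase(pop, SumObjective(), UNIT_DOM, True, rng)
        # row 0 (worse, f0 > f1): sign +1, moves toward 0.2 and improves -> accepted
        np.testing.assert_allclose(pop.X[0], 0.8 + rl * (0.2 - 0.8), atol=1e-12)
        # row 1 (better): sign -1, moves away to -0.1, wraps alpha/theta to 0.9
        # and clamps the rest to 0 -> cost 1.8 > 1.2, rejected
        np.testing.assert_array_equal(pop.X[1], X[1])
        assert pop.costs[1] == 1.2

    def test_needs_two_individuals(self, rng):
        pop = Population(X=np.zeros((1, 6)), costs=np.zeros(1))
        with pytest.raises(ValueError):
            collaborative_phase(pop, SumObjective(), UNIT_DOM, True, rng)


class TestSelfGuidingPhase:
    def test_r3_half_leaves_variables_unchanged(self):
        X = np.random.default_rng(4).uniform(size=(3, 6))
        pop = Population(X=X.copy(), costs=np.sum(X, axis=1))
        rng = ScriptedRng([np.full((3, 6), 0.5)])
        self_guiding_phase(pop, SumObjective(), UNIT_DOM, True, 20.0, rng)
        np.testing.assert_allclose(pop.X, X, atol=1e-12)

    def test_extreme_r3_stays_inside_bounds(self):
        X = np.full((2, 6), 0.5)
        pop = Population(X=X.copy(), costs=np.full(2, 3.0))
        rng = ScriptedRng([np.vstack([np.full(6, 1e-12), np.full(6, 1 - 1e-12)])])
        self_guiding_phase(pop, SumObjective(), UNIT_DOM, True, 20.0, rng)
        assert np.all(pop.X >= 0) and np.all(pop.X <= 1)

    def test_mutant_distribution_matches_reference_sampler(self):
        """Empirical mutants vs an independently coded polynomial-mutation
        sampler (distribution index 20), two-sample KS distance < 0.01."""
        n, x0, n_m = 100_000, 0.3, 20.0
        pop = Population(X=np.full((n, 6), x0), costs=np.full(n, np.inf))
        recorder = RecordingObjective()
        self_guiding_phase(pop, recorder, UNIT_DOM, True, n_m,
                           np.random.default_rng(99))
        mutants = recorder.seen[0][:, 3]  # a clamp-projected translation variable

        u = np.random.default_rng(7).uniform(size=n)
        delta = np.where(u <= 0.5,
                         (2 * u) ** (1 / (n_m + 1)) - 1,
                         1 - (2 * (1 - u)) ** (1 / (n_m + 1)))
        reference = x0 + np.where(u <= 0.5, delta * (x0 - 0.0), delta * (1.0 - x0))
        assert ks_2samp(mutants, reference).statistic < 0.01


class TestResolveDuplicates:
    def test_identical_population_becomes_distinct(self, rng):
        pop = Population(X=np.full((5, 6), 0.5), costs=np.full(5, 3.0))
        resolve_duplicates(pop, UNIT_DOM, rng, SumObjective())
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.allclose(pop.X[i], pop.X[j], atol=1e-12)
        assert pop.dup_evals == 4  # one of each duplicated pair re-evaluated

    def test_distinct_population_unchanged(self, rng):
        X = np.random.default_rng(8).uniform(size=(5, 6))
        pop = Population(X=X.copy(), costs=np.sum(X, axis=1))
        resolve_duplicates(pop, UNIT_DOM, rng, SumObjective())
        np.testing.assert_array_equal(pop.X, X)
        assert pop.dup_evals == 0

    def test_perturbation_bounded_by_one_percent_of_range(self, rng):
        pop = Population(X=np.full((2, 6), 0.5), costs=np.full(2, 3.0))
        resolve_duplicates(pop, UNIT_DOM, rng, SumObjective())
        assert np.all(np.abs(pop.X - 0.5) <= 0.01 + 1e-15)


class TestRunGopharm:
    def test_eval_accounting_and_history_shape(self):
        cfg = GOPharmConfig(N=10, M_iter=50)
        res = run_gopharm(SphereObjective(), UNIT_DOM, cfg, rng=1)
        assert res.phase_evals == 3 * 10 * 50
        assert res.init_evals == 10
        assert len(res.history) == 51

    def test_history_non_increasing(self):
        cfg = GOPharmConfig(N=10, M_iter=100)
        res = run_gopharm(SphereObjective(), UNIT_DOM, cfg, rng=2)
        assert np.all(np.diff(res.history) <= 0)

    def test_seed_determinism(self):
        cfg = GOPharmConfig(N=10, M_iter=50)
        a = run_gopharm(SphereObjective(), UNIT_DOM, cfg, rng=7)
        b = run_gopharm(SphereObjective(), UNIT_DOM, cfg, rng=7)
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.best.pose.as_array(), b.best.pose.as_array())
        assert a.best.cost == b.best.cost

    def test_sphere_beats_exhaustive_grid_search(self):
        """Default-budget run vs a 10^6-point grid-search oracle."""
        dom = SearchDomain.from_translation_bounds((3.0, 3.0, 3.0))
        obj = SphereObjective()
        res = run_gopharm(obj, dom, GOPharmConfig(), rng=3)
        axes = [np.linspace(dom.lower[j], dom.upper[j], 10) for j in range(6)]
        grids = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
        grid_best = float(obj.batch(grids).min())
        assert res.best.cost < 1e-2
        assert res.best.cost <= grid_best

    def test_poses_in_bounds_and_axis_lock_throughout(self):
        dom = SearchDomain.from_translation_bounds((2.0, 2.0, 2.0))
        cfg = GOPharmConfig(N=10, M_iter=200)
        snapshots = []

        def audit(k, pop, axis_free):
            assert np.all(pop.X >= dom.lower - 1e-12)
            assert np.all(pop.X <= dom.upper + 1e-12)
            snapshots.append((axis_free, pop.X[:, 1:3].copy()))

        run_gopharm(SphereObjective(), dom, cfg, rng=11, callback=audit)
        locked_transitions = 0
        for prev, cur in zip(snapshots, snapshots[1:]):
            if not cur[0]:  # axis held during this iteration
                np.testing.assert_array_equal(cur[1], prev[1])
                locked_transitions += 1
        assert locked_transitions > 0  # the lock was actually exercised
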
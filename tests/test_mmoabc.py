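"""Bee-colony optimizer: update rules by hand, grid/deletion arithmetic,
Pareto-front recovery on an analytic stub, and step-for-step equivalence
with a classical single-objective ABC when the momentum is off."""

import numpy as np
import pytest

from smpcnn import mmoabc
from smpcnn.mmoabc import FoodSource, OptimizerConfig


class TestInitPopulation:
    def test_within_bounds_and_deterministic(self):
        cfg = OptimizerConfig(NP=10, bounds=((0.0, 1.0),) * 3)
        pop1 = mmoabc.init_population(cfg, np.random.default_rng(5))
        pop2 = mmoabc.init_population(cfg, np.random.default_rng(5))
        for s1, s2 in zip(pop1, pop2):
            assert np.all((0 <= s1.x) & (s1.x <= 1))
            np.testing.assert_array_equal(s1.x, s2.x)
            assert np.all(s1.a == 0) and np.all(s1.b == 0)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(bounds=((0.5, 0.5), (0, 1), (0, 1)))


class TestUpdateRules:
    def test_employed_hand_value(self):
        src = FoodSource(x=np.array([0.5, 0.5, 0.5]), a=np.array([0.1, 0.0, 0.0]))
        partner = FoodSource(x=np.array([0.2, 0.2, 0.2]))
        cand = mmoabc.employed_update(src, partner, j=0, r=1.0, gamma=0.9,
                                      bounds=((0.0, 1.0),) * 3)
        assert cand.a[0] == pytest.approx(0.39)
        assert cand.x[0] == pytest.approx(0.89)
        np.testing.assert_array_equal(cand.x[1:], src.x[1:])

    def test_employed_momentum_free_is_classical_step(self):
        src = FoodSource(x=np.array([0.5, 0.4, 0.3]), a=np.array([0.7, 0.7, 0.7]))
        partner = FoodSource(x=np.array([0.1, 0.1, 0.1]))
        cand = mmoabc.employed_update(src, partner, j=1, r=-0.5, gamma=0.0,
                                      bounds=((0.0, 1.0),) * 3)
        assert cand.x[1] == pytest.approx(0.4 + (-0.5) * (0.4 - 0.1))

    def test_employed_zero_step_keeps_position(self):
        src = FoodSource(x=np.array([0.5, 0.5, 0.5]))
        partner = FoodSource(x=np.array([0.9, 0.9, 0.9]))
        cand = mmoabc.employed_update(src, partner, j=2, r=0.0, gamma=0.9,
                                      bounds=((0.0, 1.0),) * 3)
        np.testing.assert_array_equal(cand.x, src.x)

    def test_onlooker_hand_value(self):
        src = FoodSource(x=np.array([0.5, 0.5, 0.5]), b=np.array([0.2, 0.0, 0.0]))
        partner = FoodSource(x=np.array([0.3, 0.3, 0.3]))
        cand = mmoabc.onlooker_update(src, partner, j=0, r=0.0, gamma=0.9,
                                      bounds=((0.0, 1.0),) * 3)
        assert cand.b[0] == pytest.approx(0.18)
        assert cand.x[0] == pytest.approx(0.68)

    def test_onlooker_coincides_with_employed_at_zero_memory(self):
        src = FoodSource(x=np.array([0.5, 0.5, 0.5]))
        partner = FoodSource(x=np.array([0.2, 0.9, 0.4]))
        for j, r in [(0, 0.7), (1, -0.3), (2, 1.0)]:
            ce = mmoabc.employed_update(src, partner, j, r, 0.9, ((0.0, 1.0),) * 3)
            co = mmoabc.onlooker_update(src, partner, j, r, 0.9, ((0.0, 1.0),) * 3)
            np.testing.assert_allclose(ce.x, co.x)

    def test_out_of_range_dimension(self):
        src = FoodSource(x=np.zeros(3))
        with pytest.raises(IndexError):
            mmoabc.employed_update(src, src.copy(), j=5, r=0.1, gamma=0.9)


class TestOnlookerProbability:
    def test_best_in_both_objectives_is_one(self):
        probs = mmoabc.onlooker_probability(np.array([[2.0, 4.0], [1.0, 2.0]]))
        assert probs[0] == pytest.approx(1.0)

    def test_half_ratio_hand_value(self):
        probs = mmoabc.onlooker_probability(np.array([[1.0, 2.0], [2.0, 2.0]]))
        assert probs[0] == pytest.approx(0.775)

    def test_identical_sources_all_one(self):
        probs = mmoabc.onlooker_probability(np.full((4, 2), 3.0))
        np.testing.assert_allclose(probs, 1.0)

    def test_negative_fitness_guard(self):
        probs = mmoabc.onlooker_probability(np.array([[-1.0, 1.0], [-2.0, 2.0]]))
        assert np.all((0 < probs) & (probs <= 1))


class TestGridAndDeletion:
    def test_single_member_bin_zero(self):
        bins = mmoabc.grid_index(np.array([[0.4, 0.7]]), n_grid=5)
        np.testing.assert_array_equal(bins, [[0, 0]])

    def test_edge_enumeration_example(self):
        # low 0, high 1, nGrid 4 -> finite edges (0.25, 0.5, 0.75)
        vals = np.array([[0.0], [0.6], [1.0], [0.2]])
        bins = mmoabc.grid_index(vals, n_grid=4)
        np.testing.assert_array_equal(bins.ravel(), [0, 2, 3, 0])

    def test_deletion_probability_brute_force_example(self):
        bins = np.array([[0, 0], [1, 1], [3, 3]])
        poss, weight = mmoabc.deletion_probability(bins)
        np.testing.assert_array_equal(poss, [8, 6, 10])
        np.testing.assert_allclose(weight, [1 / 9, 1 / 7, 1 / 11])

    def test_identical_grid_rows(self):
        poss, weight = mmoabc.deletion_probability(np.array([[2, 2], [2, 2]]))
        np.testing.assert_array_equal(poss, [0, 0])
        np.testing.assert_array_equal(weight, [1.0, 1.0])


def stub_objective(x):
    """Analytic bi-objective with a known front: maximize (x1, 1 - x1^2)."""
    return (x[0], 1.0 - x[0] ** 2)


def grid_front(n=10_000):
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([t, 1.0 - t ** 2])


class TestOptimize:
    def test_zero_cycles_archive_is_nondominated_initial_subset(self):
        cfg = OptimizerConfig(NP=12, max_cycle=0, bounds=((0.0, 1.0),) * 3, seed=3)
        archive, _ = mmoabc.optimize(cfg, stub_objective)
        fits = archive.fitness_matrix()
        for i in range(len(fits)):
            for j in range(len(fits)):
                assert not mmoabc.dominates(fits[j], fits[i], cfg.senses)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_stub_front_recovery(self, seed):
        cfg = OptimizerConfig(NP=20, max_cycle=50, bounds=((0.0, 1.0),) * 3,
                              rep=20, seed=seed)
        archive, triplet = mmoabc.optimize(cfg, stub_objective)
        assert len(archive.members) >= 1
        front = grid_front()
        for member in archive.members:
            f = np.asarray(member.fitness)
            dominated = np.all(front >= f + 0.02, axis=1) & np.any(front > f + 0.02, axis=1)
            assert not np.any(dominated)
            assert np.all((0 <= member.x) & (member.x <= 1))

    def test_fixed_seed_reproducibility(self):
        cfg = OptimizerConfig(NP=10, max_cycle=10, bounds=((0.0, 1.0),) * 3, seed=11)
        a1, t1 = mmoabc.optimize(cfg, stub_objective)
        a2, t2 = mmoabc.optimize(cfg, stub_objective)
        np.testing.assert_array_equal(t1, t2)
        assert len(a1.members) == len(a2.members)
        for m1, m2 in zip(a1.members, a2.members):
            np.testing.assert_array_equal(m1.x, m2.x)

    def test_failed_evaluation_gets_worst_fitness(self):
        def flaky(x):
            if x[0] < 0.5:
                raise RuntimeError("boom")
            return (x[0], 1 - x[0] ** 2)

        cfg = OptimizerConfig(NP=8, max_cycle=5, bounds=((0.0, 1.0),) * 3, seed=2)
        archive, _ = mmoabc.optimize(cfg, flaky)
        for m in archive.members:
            assert np.all(np.asarray(m.fitness) > -1e17)

    def test_archive_nondominance_after_run(self):
        cfg = OptimizerConfig(NP=15, max_cycle=20, bounds=((0.0, 1.0),) * 3, seed=7)
        archive, _ = mmoabc.optimize(cfg, stub_objective)
        fits = archive.fitness_matrix()
        for i in range(len(fits)):
            for j in range(len(fits)):
                assert not mmoabc.dominates(fits[j], fits[i], cfg.senses)


def classical_abc(objective, NP, d, limit, max_cycle, bounds, seed):
    """Reference single-objective ABC (greedy maximization, roulette
    onlookers, one scout per cycle) written as plain loops."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    xs = [lo + rng.uniform(0.0, 1.0, size=d) * (hi - lo) for _ in range(NP)]
    fs = [objective(x) for x in xs]
    trials = [0] * NP

    def try_step(i, k, j, r):
        cand = xs[i].copy()
        cand[j] = cand[j] + r * (xs[i][j] - xs[k][j])
        cand = np.clip(cand, lo, hi)
        fc = objective(cand)
        if fc > fs[i]:
            xs[i], fs[i], trials[i] = cand, fc, 0
        else:
            trials[i] += 1

    for _ in range(max_cycle):
        for i in range(NP):
            j = int(rng.integers(d))
            k = int(rng.integers(NP - 1))
            k = k + 1 if k >= i else k
            r = rng.uniform(-1.0, 1.0)
            try_step(i, k, j, r)
        f = np.array(fs, dtype=float)
        if f.min() <= 0:
            f = f - f.min() + 1e-9
        probs = 0.9 * f / f.max() + 0.1
        cum = np.cumsum(probs)
        for _ in range(NP):
            u = rng.uniform(0.0, cum[-1])
            i = int(np.searchsorted(cum, u, side="left"))
            j = int(rng.integers(d))
            k = int(rng.integers(NP - 1))
            k = k + 1 if k >= i else k
            r = rng.uniform(-1.0, 1.0)
            try_step(i, k, j, r)
            cum = np.cumsum(probs)  # probabilities fixed within the phase
        worst = int(np.argmax(trials))
        if trials[worst] > limit:
            xs[worst] = lo + rng.uniform(0.0, 1.0, size=d) * (hi - lo)
            fs[worst] = objective(xs[worst])
            trials[worst] = 0
    return xs, fs


def test_momentum_free_single_objective_matches_classical_abc():
    """With gamma=0 and one objective the colony is a classical ABC: the
    final populations agree exactly under a shared RNG stream."""

    def single(x):
        return 1.0 / (1.0 + np.sum((np.asarray(x) - 0.3) ** 2))

    bounds = ((0.0, 1.0),) * 3
    cfg = OptimizerConfig(NP=8, limit=10, max_cycle=15, gamma=0.0,
                          bounds=bounds, senses=(1,), rep=5, seed=21)

    # run the package optimizer but keep hold of the evolving population
    # (optimize mutates the list returned by init_population in place)
    holder = {}
    original = mmoabc.init_population

    def capture_init(config, rng):
        holder["pop"] = original(config, rng)
        return holder["pop"]

    mmoabc.init_population = capture_init
    try:
        mmoabc.optimize(cfg, lambda x: (single(x),))
    finally:
        mmoabc.init_population = original
    ours = sorted(tuple(np.round(s.x, 12)) for s in holder["pop"])

    xs, _ = classical_abc(single, NP=8, d=3, limit=10, max_cycle=15,
                          bounds=bounds, seed=21)
    theirs = sorted(tuple(np.round(x, 12)) for x in xs)
    assert ours == theirs
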
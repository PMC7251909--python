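import numpy as np
import pytest

from pcsnp.ga_select import (
    GAConfig,
    Individual,
    evolve,
    init_population,
    multipoint_crossover,
    mutate_conventional,
    mutate_modified,
    roulette_select,
)


class TestGAConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pop_size": 1},
            {"p_crossover": 1.5},
            {"p_mutation": -0.1},
            {"max_generations": 0},
            {"mode": "fancy"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GAConfig(**kwargs)


class TestInitPopulation:
    def test_all_ones_at_init_p_one(self):
        rng = np.random.default_rng(0)
        pop = init_population(8, GAConfig(pop_size=5, init_p=1.0), rng)
        assert all(ind.mask.all() for ind in pop)

    def test_empty_masks_repaired_to_single_bit(self):
        rng = np.random.default_rng(0)
        pop = init_population(10, GAConfig(pop_size=6, init_p=0.0), rng)
        assert all(ind.n_selected == 1 for ind in pop)

    def test_mean_fraction_near_init_p_within_3_sigma(self):
        d, p = 1000, 0.5
        rng = np.random.default_rng(1)
        pop = init_population(d, GAConfig(pop_size=10, init_p=p), rng)
        total = sum(ind.n_selected for ind in pop)
        n = 10 * d
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(total - n * p) <= 3 * sigma

    def test_deterministic_for_fixed_seed(self):
        pops = [
            init_population(20, GAConfig(pop_size=4), np.random.default_rng(9))
            for _ in range(2)
        ]
        for a, b in zip(*pops):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            init_population(0, GAConfig(), np.random.default_rng(0))


class TestRouletteSelect:
    def _pop(self, fitnesses, d=4):
        return [Individual(np.ones(d, bool), f) for f in fitnesses]

    def test_zero_fitness_parent_never_drawn_first(self):
        rng = np.random.default_rng(2)
        pop = self._pop([1.0, 0.0])
        for _ in range(200):
            first, second = roulette_select(pop, rng)
            assert first is pop[0]
            assert second is pop[1]  # distinct second parent

    def test_equal_fitness_draws_uniform_within_3_sigma(self):
        rng = np.random.default_rng(3)
        pop = self._pop([0.5, 0.5, 0.5, 0.5])
        draws = 4000
        counts = np.zeros(4)
        for _ in range(draws):
            first, _ = roulette_select(pop, rng)
            counts[next(i for i, ind in enumerate(pop) if ind is first)] += 1
        expected = draws / 4
        sigma = np.sqrt(draws * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) <= 3 * sigma)

    def test_selection_frequency_proportional_to_fitness(self):
        rng = np.random.default_rng(4)
        pop = self._pop([3.0, 1.0])
        draws = 10_000
        hits = sum(roulette_select(pop, rng)[0] is pop[0] for _ in range(draws))
        p = 0.75
        sigma = np.sqrt(draws * p * (1 - p))
        assert abs(hits - draws * p) <= 3 * sigma

    def test_unevaluated_individual_rejected(self):
        pop = [Individual(np.ones(3, bool), 0.5), Individual(np.ones(3, bool))]
        with pytest.raises(ValueError, match="evaluated"):
            roulette_select(pop, np.random.default_rng(0))


class _StubRng:
    """Minimal rng standing in for numpy's Generator in crossover tests."""

    def __init__(self, cuts):
        self._cuts = np.asarray(cuts)

    def random(self):
        return 0.0  # always below p_crossover

    def choice(self, a, size, replace):
        return self._cuts[:size]


class TestCrossover:
    def test_manual_two_point_segment_swap(self):
        a = Individual(np.array([1, 1, 1, 1, 1, 1], bool))
        b = Individual(np.array([0, 0, 0, 0, 0, 0], bool))
        c1, c2 = multipoint_crossover(a, b, GAConfig(), _StubRng([2, 4]))
        np.testing.assert_array_equal(c1.mask.astype(int), [1, 1, 0, 0, 1, 1])
        np.testing.assert_array_equal(c2.mask.astype(int), [0, 0, 1, 1, 0, 0])

    def test_identical_parents_give_identical_children(self):
        rng = np.random.default_rng(5)
        a = Individual(np.array([1, 0, 1, 0, 1], bool))
        c1, c2 = multipoint_crossover(a, a.copy(), GAConfig(), rng)
        np.testing.assert_array_equal(c1.mask, a.mask)
        np.testing.assert_array_equal(c2.mask, a.mask)

    def test_no_crossover_at_zero_rate(self):
        rng = np.random.default_rng(6)
        a = Individual(np.array([1, 1, 0, 0], bool))
        b = Individual(np.array([0, 0, 1, 1], bool))
        c1, c2 = multipoint_crossover(a, b, GAConfig(p_crossover=0.0), rng)
        np.testing.assert_array_equal(c1.mask, a.mask)
        np.testing.assert_array_equal(c2.mask, b.mask)

    def test_positionwise_bits_conserved(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = Individual(rng.random(30) < 0.5)
            b = Individual(rng.random(30) < 0.5)
            c1, c2 = multipoint_crossover(a, b, GAConfig(), rng)
            np.testing.assert_array_equal(
                c1.mask.astype(int) + c2.mask.astype(int),
                a.mask.astype(int) + b.mask.astype(int),
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multipoint_crossover(
                Individual(np.ones(3, bool)),
                Individual(np.ones(4, bool)),
                GAConfig(),
                np.random.default_rng(0),
            )


class TestMutation:
    def test_conventional_extremes(self):
        rng = np.random.default_rng(8)
        ind = Individual(np.array([1, 0, 1, 0], bool))
        np.testing.assert_array_equal(
            mutate_conventional(ind, 0.0, rng).mask, ind.mask
        )
        np.testing.assert_array_equal(
            mutate_conventional(ind, 1.0, rng).mask, ~ind.mask
        )

    def test_modified_extremes(self):
        rng = np.random.default_rng(9)
        ind = Individual(np.array([1, 0, 1, 0], bool))
        np.testing.assert_array_equal(mutate_modified(ind, 0.0, rng).mask, ind.mask)
        assert mutate_modified(ind, 1.0, rng).mask.all()

    def test_conventional_preserves_half_density(self):
        # flip symmetry: from density 0.5 the expected density stays 0.5
        d = 10_000
        rng = np.random.default_rng(10)
        ind = Individual(rng.random(d) < 0.5)
        for p_m in (0.1, 0.5, 0.9):
            out = mutate_conventional(ind, p_m, rng)
            sigma = np.sqrt(d * 0.25)
            assert abs(out.n_selected - d / 2) <= 4 * sigma

    @pytest.mark.parametrize("p_m", [0.2, 0.9])
    def test_modified_stationary_density_approaches_p_m(self, p_m):
        # fixed point of x -> (1 - p_m) x + p_m^2 is x = p_m
        d = 10_000
        rng = np.random.default_rng(11)
        ind = Individual(rng.random(d) < 0.5)
        for _ in range(40):
            ind = mutate_modified(ind, p_m, rng)
        assert ind.n_selected / d == pytest.approx(p_m, abs=0.03)


class TestEvolve:
    def test_bit_counting_fitness_improves_and_is_monotone(self):
        cfg = GAConfig(pop_size=10, max_generations=10, seed=1)
        result = evolve(20, cfg, lambda mask: mask.mean())
        best = [h["best_fitness"] for h in result.history]
        assert best == sorted(best)
        assert best[-1] >= best[0]
        assert result.best.fitness == best[-1]

    def test_single_generation_runs_one_cycle(self):
        cfg = GAConfig(pop_size=4, max_generations=1, seed=2)
        result = evolve(6, cfg, lambda mask: mask.mean())
        assert len(result.history) == 2  # initial + one generation

    def test_same_seed_same_best_mask(self):
        cfg = GAConfig(pop_size=6, max_generations=5, seed=3, mode="modified")
        r1 = evolve(15, cfg, lambda mask: mask.mean())
        r2 = evolve(15, cfg, lambda mask: mask.mean())
        np.testing.assert_array_equal(r1.best.mask, r2.best.mask)

    def test_fitness_errors_carry_generation_context(self):
        def bad_fitness(mask):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="generation"):
            evolve(5, GAConfig(pop_size=4, seed=0), bad_fitness)

    def test_conventional_neutral_fitness_keeps_half_density(self):
        # neutral fitness: selection exerts no pressure on mask size
        fractions = []
        for seed in range(10):
            cfg = GAConfig(pop_size=10, max_generations=10, seed=seed, p_mutation=0.5)
            result = evolve(400, cfg, lambda mask: 0.5)
            fractions.append(result.best.mask.mean())
        assert 0.4 <= np.mean(fractions) <= 0.6

    def test_modified_mask_sizes_increase_with_p_m(self):
        from scipy.stats import mannwhitneyu

        sizes = {}
        for p_m in (0.1, 0.9):
            sizes[p_m] = []
            for seed in range(20):
                cfg = GAConfig(
                    pop_size=8, max_generations=8, seed=seed,
                    p_mutation=p_m, mode="modified",
                )
                sizes[p_m].append(evolve(200, cfg, lambda mask: 0.5).best.n_selected)
        stat = mannwhitneyu(sizes[0.9], sizes[0.1], alternative="greater")
        assert stat.pvalue < 0.01
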
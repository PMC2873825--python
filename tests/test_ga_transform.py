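import numpy as np
import pytest

from gacontact.ga_transform import (
    GaConfig,
    apply_matrix,
    apply_transformation,
    assign_nearest_centroid,
    centroid_functions,
    compile_chromosome,
    crossover_single_point,
    fitness,
    mutate,
    roulette_select,
    run_ga,
)
from gacontact.synthetic import planted_separation_dataset


def naive_transform(chromosome: str, values) -> np.ndarray:
    """Independent single-pass interpreter of the remove/merge grammar."""
    out = []
    prev_char = None
    for ch, v in zip(chromosome, values):
        if ch == "a":
            prev_char = None
            continue
        if ch == prev_char:
            out[-1] += v
        else:
            out.append(float(v))
        prev_char = ch
    out = np.asarray(out, dtype=float)
    total = out.sum()
    return out / total if total > 0 else out


class TestCompile:
    def test_worked_example_cbbabcca(self):
        t = compile_chromosome("cbbabcca")
        assert t.n_features == 4
        assert t.removed == frozenset({3, 7})  # 0-based positions 4 and 8
        assert t.groups == ((0,), (1, 2), (4,), (5, 6))

    def test_all_removed(self):
        t = compile_chromosome("aaaa")
        assert t.groups == ()
        assert t.removed == frozenset({0, 1, 2, 3})

    def test_character_change_breaks_run(self):
        t = compile_chromosome("bcb")
        assert t.groups == ((0,), (1,), (2,))

    def test_long_run_merges_as_one_group(self):
        t = compile_chromosome("bbbb")
        assert t.groups == ((0, 1, 2, 3),)

    def test_a_breaks_run(self):
        t = compile_chromosome("bab")
        assert t.groups == ((0,), (2,))

    def test_partition_invariant(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            chrom = "".join("abc"[k] for k in rng.integers(0, 3, m))
            t = compile_chromosome(chrom)
            flat = sorted([i for g in t.groups for i in g] + list(t.removed))
            assert flat == list(range(m))

    def test_illegal_character(self):
        with pytest.raises(ValueError, match="illegal"):
            compile_chromosome("abx")


class TestApply:
    def test_worked_example_values(self):
        t = compile_chromosome("cbbabcca")
        out = apply_transformation(t, np.ones(8))
        np.testing.assert_allclose(out, [1 / 6, 2 / 6, 1 / 6, 2 / 6])

    def test_all_b_single_feature(self):
        t = compile_chromosome("bbbbb")
        out = apply_transformation(t, np.array([0.1, 0.2, 0.3, 0.2, 0.2]))
        np.testing.assert_allclose(out, [1.0])

    def test_all_zero_stays_zero(self):
        t = compile_chromosome("bcb")
        out = apply_transformation(t, np.zeros(3))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_dimension_mismatch(self):
        t = compile_chromosome("bcb")
        with pytest.raises(ValueError, match="length 3"):
            apply_transformation(t, np.ones(4))

    def test_oracle_equivalence_random(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 50))
            chrom = "".join("abc"[k] for k in rng.integers(0, 3, m))
            v = rng.random(m)
            t = compile_chromosome(chrom)
            expected = naive_transform(chrom, v)
            got = apply_transformation(t, v)
            assert got.shape == expected.shape
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_mass_conservation_pre_normalization(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 40))
            chrom = "".join("abc"[k] for k in rng.integers(0, 3, m))
            t = compile_chromosome(chrom)
            if not t.groups:
                continue
            v = rng.random(m)
            kept_mass = sum(v[i] for g in t.groups for i in g)
            pre = [sum(v[i] for i in g) for g in t.groups]
            assert sum(pre) == pytest.approx(kept_mass)


IDENTITY_6 = "bcbcbc"  # alternating -> all singleton groups


class TestCentroids:
    def test_identity_centroids_equal_class_means(self, rng):
        t = compile_chromosome(IDENTITY_6)
        pos = rng.dirichlet(np.ones(6), size=10)
        neg = rng.dirichlet(np.ones(6), size=12)
        c1, c0 = centroid_functions(t, pos, neg)
        np.testing.assert_allclose(c1, pos.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(c0, neg.mean(axis=0), atol=1e-12)

    def test_single_sample_per_class(self, rng):
        t = compile_chromosome("bbcacb")
        p = rng.dirichlet(np.ones(6))
        n = rng.dirichlet(np.ones(6))
        c1, c0 = centroid_functions(t, p, n)
        np.testing.assert_allclose(c1, apply_transformation(t, p))
        np.testing.assert_allclose(c0, apply_transformation(t, n))

    def test_oracle_mean_200_samples(self, rng):
        t = compile_chromosome("".join("abc"[k] for k in rng.integers(0, 3, 20)))
        pos = rng.dirichlet(np.ones(20), size=120)
        neg = rng.dirichlet(np.ones(20), size=80)
        c1, c0 = centroid_functions(t, pos, neg)
        np.testing.assert_allclose(c1, apply_matrix(t, pos).mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(c0, apply_matrix(t, neg).mean(axis=0), atol=1e-12)

    def test_empty_class_error(self, rng):
        t = compile_chromosome(IDENTITY_6)
        with pytest.raises(ValueError, match="empty class"):
            centroid_functions(t, np.empty((0, 6)), rng.dirichlet(np.ones(6), size=3))


class TestAssign:
    def test_exact_centroid_match(self):
        t = compile_chromosome(IDENTITY_6)
        c1 = np.eye(6)[0]
        c0 = np.eye(6)[1]
        assert assign_nearest_centroid(t, c1, c1, c0) == 1
        assert assign_nearest_centroid(t, c0, c1, c0) == 0

    def test_tie_goes_to_class_0(self):
        t = compile_chromosome("bc")
        c1 = np.array([1.0, 0.0])
        c0 = np.array([0.0, 1.0])
        x = np.array([0.5, 0.5])
        assert assign_nearest_centroid(t, x, c1, c0) == 0

    def test_brute_force_1000(self, rng):
        t = compile_chromosome("".join("abc"[k] for k in rng.integers(0, 3, 12)))
        c1 = rng.dirichlet(np.ones(t.n_features))
        c0 = rng.dirichlet(np.ones(t.n_features))
        X = rng.dirichlet(np.ones(12), size=1000)
        for x in X:
            tx = apply_transformation(t, x)
            expected = int(np.linalg.norm(tx - c1) < np.linalg.norm(tx - c0))
            assert assign_nearest_centroid(t, x, c1, c0) == expected


def brute_force_fitness(chromosome, X, y):
    t = compile_chromosome(chromosome)
    if not t.groups:
        return 0
    T = np.array([naive_transform(chromosome, x) for x in X])
    c1 = T[y == 1].mean(axis=0)
    c0 = T[y == 0].mean(axis=0)
    correct = 0
    for tx, label in zip(T, y):
        d1 = np.linalg.norm(tx - c1)
        d0 = np.linalg.norm(tx - c0)
        assigned = 1 if d1 < d0 else 0
        correct += int(assigned == label)
    return correct


class TestFitness:
    def test_perfect_separation_max(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        y = np.array([1, 1, 0, 0])
        assert fitness("bc", X, y) == 4

    def test_all_a_zero(self, rng):
        X = rng.dirichlet(np.ones(5), size=10)
        y = np.array([1] * 5 + [0] * 5)
        assert fitness("aaaaa", X, y) == 0

    def test_coincident_classes_collapse(self, rng):
        # identical feature distribution in both classes: nearest-centroid
        # assignments are near-arbitrary; fitness lands near max(|C1|,|C0|)
        X = np.vstack([rng.dirichlet(np.ones(5), size=10)] * 2)
        y = np.array([1] * 10 + [0] * 10)
        f = fitness("bcbcb", X, y)
        assert 5 <= f <= 15

    def test_brute_force_20_sample_instances(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 15))
            chrom = "".join("abc"[k] for k in rng.integers(0, 3, m))
            X = rng.dirichlet(np.ones(m), size=20)
            y = np.concatenate([np.ones(10, int), np.zeros(10, int)])
            assert fitness(chrom, X, y) == brute_force_fitness(chrom, X, y)

    def test_single_class_error(self, rng):
        X = rng.dirichlet(np.ones(4), size=6)
        with pytest.raises(ValueError, match="both classes"):
            fitness("bcbc", X, np.ones(6, int))

    def test_bounds(self, rng):
        for _ in range(20):
            chrom = "".join("abc"[k] for k in rng.integers(0, 3, 10))
            X = rng.dirichlet(np.ones(10), size=14)
            y = np.concatenate([np.ones(7, int), np.zeros(7, int)])
            assert 0 <= fitness(chrom, X, y) <= 14


class _FixedCutRng:
    """Minimal rng stub forcing a specific crossover cut."""

    def __init__(self, cut):
        self.cut = cut

    def integers(self, lo, hi=None):
        return self.cut


class TestOperators:
    def test_crossover_identical_parents(self, rng):
        c1, c2 = crossover_single_point("abcabc", "abcabc", rng)
        assert c1 == c2 == "abcabc"

    def test_crossover_cut_at_1(self):
        c1, c2 = crossover_single_point("aaa", "bbb", _FixedCutRng(1))
        assert (c1, c2) == ("abb", "baa")

    def test_crossover_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            crossover_single_point("ab", "abc", rng)

    def test_crossover_preserves_positionwise_characters(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 30))
            p1 = "".join("abc"[k] for k in rng.integers(0, 3, m))
            p2 = "".join("abc"[k] for k in rng.integers(0, 3, m))
            c1, c2 = crossover_single_point(p1, p2, rng)
            for k in range(m):
                assert {c1[k], c2[k]} == {p1[k], p2[k]}

    def test_mutate_p0_identity(self, rng):
        chrom = "abcabcabc"
        assert mutate(chrom, 0.0, rng) == chrom

    def test_mutate_p1_all_changed(self, rng):
        chrom = "abc" * 30
        mutated = mutate(chrom, 1.0, rng)
        assert all(a != b for a, b in zip(chrom, mutated))

    def test_mutate_empirical_rate(self, rng):
        chrom = "a" * 100_000
        mutated = mutate(chrom, 0.01, rng)
        changed = sum(a != b for a, b in zip(chrom, mutated))
        # binomial(1e5, 0.01): mean 1000, sd ~31.5; 5 sigma band
        assert 840 < changed < 1160

    def test_roulette_degenerate(self, rng):
        for _ in range(100):
            assert roulette_select(["x", "y"], [1.0, 0.0], rng) == "x"

    def test_roulette_uniform_5050(self, rng):
        picks = sum(roulette_select([1, 0], [1.0, 1.0], rng) for _ in range(10_000))
        assert 4800 < picks < 5200  # 3 sigma ~ 150

    def test_roulette_75_25(self, rng):
        picks = sum(roulette_select([1, 0], [3.0, 1.0], rng) for _ in range(10_000))
        assert 7300 < picks < 7700

    def test_roulette_all_zero_uniform_fallback(self, rng):
        picks = sum(roulette_select([1, 0], [0.0, 0.0], rng) for _ in range(10_000))
        assert 4800 < picks < 5200


class TestRunGa:
    def test_planted_separable_reaches_max(self):
        hits = 0
        for seed in range(10):
            X, y = planted_separation_dataset(
                20, 20, 4, 8, separation=0.8, rng=np.random.default_rng(100 + seed)
            )
            cfg = GaConfig(
                population_size=30,
                stall_generations=15,
                max_generations=60,
                rng_seed=seed,
            )
            best, history = run_ga(X, y, cfg)
            if history[-1].best_fitness == len(y):
                hits += 1
        assert hits >= 9

    def test_stall_termination_exact(self, rng):
        # all vectors identical: constant fitness landscape
        X = np.tile(rng.dirichlet(np.ones(6)), (10, 1))
        y = np.array([1] * 5 + [0] * 5)
        cfg = GaConfig(population_size=8, stall_generations=5, max_generations=100, rng_seed=0)
        _, history = run_ga(X, y, cfg)
        assert len(history) == 5 + 1

    def test_seeded_determinism(self, rng):
        X, y = planted_separation_dataset(10, 10, 3, 5, 0.5, rng)
        cfg = GaConfig(population_size=10, stall_generations=5, max_generations=20, rng_seed=7)
        best1, hist1 = run_ga(X, y, cfg)
        best2, hist2 = run_ga(X, y, cfg)
        assert best1 == best2
        assert [(h.best_fitness, h.best_chromosome) for h in hist1] == [
            (h.best_fitness, h.best_chromosome) for h in hist2
        ]

    def test_elitism_monotone_best(self, rng):
        X, y = planted_separation_dataset(15, 15, 3, 10, 0.4, rng)
        cfg = GaConfig(population_size=12, stall_generations=8, max_generations=40, rng_seed=3)
        _, history = run_ga(X, y, cfg)
        bests = [h.best_fitness for h in history]
        assert all(b <= a for b, a in zip(bests, bests[1:]))

    def test_single_class_error(self, rng):
        X = rng.dirichlet(np.ones(4), size=6)
        cfg = GaConfig(population_size=4, rng_seed=0)
        with pytest.raises(ValueError, match="both classes"):
            run_ga(X, np.zeros(6, int), cfg)


class TestGaConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            GaConfig(crossover_prob=1.5)

    def test_bad_population(self):
        with pytest.raises(ValueError):
            GaConfig(population_size=1)

    def test_bad_dissimilarity(self):
        with pytest.raises(ValueError):
            GaConfig(dissimilarity="cosine")
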
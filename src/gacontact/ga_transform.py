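"""Genetic-algorithm classifier core.

A chromosome is a string over {a, b, c} of the feature dimension:
'a' removes the feature; a maximal run of identical 'b' or 'c'
characters (contiguous in the original string — an 'a' or a character
change breaks the run) merges those features into one by summation.
Transformed vectors are re-normalized to unit L1 mass.

Fitness of a chromosome on a labelled sample set: transform all
samples, compute per-class centroids, assign every sample to the class
of the nearer centroid, and count correct assignments over both
classes.  The GA (roulette selection, single-point crossover,
per-position mutation, elitism) maximizes this count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "abc"

_DISSIMILARITIES = ("euclidean", "manhattan")


@dataclass(frozen=True)
class Transformation:
    """Compiled remove/merge structure of a chromosome.

    ``groups`` are ordered runs of original 0-based indices (singleton
    = kept feature, longer = merged run); ``removed`` are the 'a'
    positions.  Together they partition 0..m-1.
    """

    m: int
    groups: tuple[tuple[int, ...], ...]
    removed: frozenset

    @property
    def n_features(self) -> int:
        return len(self.groups)

    def _kept_and_starts(self) -> tuple[np.ndarray, np.ndarray]:
        kept = np.asarray([i for g in self.groups for i in g], dtype=int)
        starts = np.cumsum([0] + [len(g) for g in self.groups[:-1]], dtype=int)
        return kept, starts


def _validate(chromosome: str) -> None:
    bad = set(chromosome) - set(ALPHABET)
    if bad:
        raise ValueError(f"illegal chromosome characters: {sorted(bad)}")


def compile_chromosome(chromosome: str) -> Transformation:
    """Parse a chromosome into its remove/merge feature groups."""
    _validate(chromosome)
    groups: list[tuple[int, ...]] = []
    removed: set[int] = set()
    run: list[int] = []
    prev = ""
    for idx, ch in enumerate(chromosome):
        if ch == "a":
            if run:
                groups.append(tuple(run))
                run = []
            removed.add(idx)
        elif ch == prev and run:
            run.append(idx)
        else:
            if run:
                groups.append(tuple(run))
            run = [idx]
        prev = ch
    if run:
        groups.append(tuple(run))
    return Transformation(m=len(chromosome), groups=tuple(groups), removed=frozenset(removed))


def apply_transformation(t: Transformation, values: np.ndarray) -> np.ndarray:
    """Apply a compiled transformation to one vector.

    Each group emits the sum of its members; the output is
    L1-normalized (an all-zero result is returned as-is).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (t.m,):
        raise ValueError(f"expected vector of length {t.m}, got {values.shape}")
    return apply_matrix(t, values[None, :])[0]


def apply_matrix(t: Transformation, X: np.ndarray) -> np.ndarray:
    """Row-wise :func:`apply_transformation` on an (n, m) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != t.m:
        raise ValueError(f"expected (n, {t.m}) matrix, got {X.shape}")
    if not t.groups:
        return np.zeros((X.shape[0], 0))
    kept, starts = t._kept_and_starts()
    out = np.add.reduceat(X[:, kept], starts, axis=1)
    totals = out.sum(axis=1, keepdims=True)
    return np.divide(out, totals, out=out, where=totals > 0)


def centroid_functions(
    t: Transformation, positives: np.ndarray, negatives: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class means of the transformed training vectors -> (c1, c0)."""
    positives = np.atleast_2d(positives)
    negatives = np.atleast_2d(negatives)
    if positives.shape[0] == 0 or negatives.shape[0] == 0:
        raise ValueError("empty class: both classes need >= 1 sample")
    return apply_matrix(t, positives).mean(axis=0), apply_matrix(t, negatives).mean(axis=0)


def _distance(a: np.ndarray, b: np.ndarray, dissimilarity: str) -> np.ndarray:
    diff = a - b
    if dissimilarity == "euclidean":
        return np.sqrt((diff * diff).sum(axis=-1))
    if dissimilarity == "manhattan":
        return np.abs(diff).sum(axis=-1)
    raise ValueError(f"unknown dissimilarity {dissimilarity!r}")


def assign_nearest_centroid(
    t: Transformation,
    x: np.ndarray,
    c1: np.ndarray,
    c0: np.ndarray,
    dissimilarity: str = "euclidean",
) -> int:
    """Class of the nearer transformed centroid; ties go to class 0."""
    tx = apply_transformation(t, x)
    d1 = _distance(tx, c1, dissimilarity)
    d0 = _distance(tx, c0, dissimilarity)
    return int(d1 < d0)


def fitness(
    chromosome: str,
    X: np.ndarray,
    y: np.ndarray,
    dissimilarity: str = "euclidean",
) -> int:
    """Nearest-centroid agreement count of a chromosome on (X, y).

    Centroids are computed from the same samples being scored; the
    maximum |C1| + |C0| is attained iff the imposed nearest-centroid
    classes coincide with the true labels.  An all-'a' chromosome
    (empty transformation) scores 0 by convention.
    """
    _validate(chromosome)
    return _fitness_compiled(compile_chromosome(chromosome), X, y, dissimilarity)


def _fitness_compiled(
    t: Transformation, X: np.ndarray, y: np.ndarray, dissimilarity: str = "euclidean"
) -> int:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("fitness requires samples from both classes")
    if not t.groups:
        return 0
    T = apply_matrix(t, X)
    c1 = T[y == 1].mean(axis=0)
    c0 = T[y == 0].mean(axis=0)
    d1 = _distance(T, c1, dissimilarity)
    d0 = _distance(T, c0, dissimilarity)
    assigned = (d1 < d0).astype(int)  # tie -> class 0
    return int((assigned == y).sum())


def crossover_single_point(
    parent1: str, parent2: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Swap suffixes at a cut position uniform in 1..m-1."""
    if len(parent1) != len(parent2):
        raise ValueError("parents must have equal length")
    _validate(parent1)
    _validate(parent2)
    m = len(parent1)
    if m < 2:
        return parent1, parent2
    cut = int(rng.integers(1, m))
    return parent1[:cut] + parent2[cut:], parent2[:cut] + parent1[cut:]


def mutate(chromosome: str, mutation_prob: float, rng: np.random.Generator) -> str:
    """Independently replace each position, with probability
    ``mutation_prob``, by a uniformly chosen different character."""
    if not 0.0 <= mutation_prob <= 1.0:
        raise ValueError("mutation_prob must be in [0, 1]")
    _validate(chromosome)
    arr = np.frombuffer(chromosome.encode(), dtype=np.uint8).copy()
    codes = arr - ord("a")
    flip = rng.random(len(arr)) < mutation_prob
    # shift by 1 or 2 mod 3 => always a different character
    shifts = rng.integers(1, 3, size=len(arr))
    codes[flip] = (codes[flip] + shifts[flip]) % 3
    return (codes + ord("a")).astype(np.uint8).tobytes().decode()


def roulette_select(population: list, fitnesses, rng: np.random.Generator):
    """Sample one individual with probability proportional to fitness;
    uniform fallback when all fitnesses are zero."""
    return population[_roulette_index(np.asarray(fitnesses, dtype=float), rng)]


def _roulette_index(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    if np.any(fitnesses < 0):
        raise ValueError("fitnesses must be non-negative")
    total = fitnesses.sum()
    if total <= 0:
        return int(rng.integers(len(fitnesses)))
    return int(rng.choice(len(fitnesses), p=fitnesses / total))


@dataclass
class GaConfig:
    """Evolutionary-loop parameters.

    Defaults: population 150, 5% elitism, single-point crossover with
    probability 0.95, per-position mutation 0.01, stop after 120
    stalled generations.
    """

    population_size: int = 150
    elite_fraction: float = 0.05
    crossover_prob: float = 0.95
    mutation_prob: float = 0.01
    stall_generations: int = 120
    max_generations: int = 2000
    dissimilarity: str = "euclidean"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("elite_fraction", "crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dissimilarity not in _DISSIMILARITIES:
            raise ValueError(f"dissimilarity must be one of {_DISSIMILARITIES}")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "elite_fraction": self.elite_fraction,
            "crossover_prob": self.crossover_prob,
            "mutation_prob": self.mutation_prob,
            "stall_generations": self.stall_generations,
            "max_generations": self.max_generations,
            "dissimilarity": self.dissimilarity,
            "rng_seed": self.rng_seed,
        }


@dataclass
class FitnessRecord:
    generation: int
    best_fitness: int
    mean_fitness: float
    best_chromosome: str = field(repr=False)


def _codes_to_str(codes: np.ndarray) -> str:
    return (codes.astype(np.uint8) + ord("a")).tobytes().decode()


def run_ga(
    X: np.ndarray, y: np.ndarray, config: GaConfig
) -> tuple[str, list[FitnessRecord]]:
    """Evolve a feature-transforming chromosome on labelled samples.

    Initial population uniform over {a,b,c}; per generation the top
    ``elite_fraction`` individuals carry over unchanged and the rest are
    produced by roulette-selected parents undergoing single-point
    crossover (prob ``crossover_prob``) then per-position mutation.
    Terminates when the best fitness has not improved for
    ``stall_generations`` consecutive generations, or at
    ``max_generations``.  Deterministic for a fixed ``rng_seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("run_ga requires samples from both classes")
    m = X.shape[1]
    rng = np.random.default_rng(config.rng_seed)
    pop_size = config.population_size
    n_elite = max(1, int(pop_size * config.elite_fraction))

    pop = rng.integers(0, 3, size=(pop_size, m), dtype=np.int8)

    def eval_pop(p: np.ndarray) -> np.ndarray:
        return np.asarray(
            [
                _fitness_compiled(
                    compile_chromosome(_codes_to_str(ind)), X, y, config.dissimilarity
                )
                for ind in p
            ]
        )

    fits = eval_pop(pop)
    order = np.argsort(-fits, kind="stable")
    history = [
        FitnessRecord(0, int(fits[order[0]]), float(fits.mean()), _codes_to_str(pop[order[0]]))
    ]
    best_fit = int(fits[order[0]])
    best_chrom = _codes_to_str(pop[order[0]])
    stall = 0

    for gen in range(1, config.max_generations + 1):
        order = np.argsort(-fits, kind="stable")
        children = [pop[i].copy() for i in order[:n_elite]]
        while len(children) < pop_size:
            i1 = _roulette_index(fits.astype(float), rng)
            i2 = _roulette_index(fits.astype(float), rng)
            c1, c2 = pop[i1].copy(), pop[i2].copy()
            if m >= 2 and rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, m))
                c1[cut:], c2[cut:] = pop[i2][cut:], pop[i1][cut:]
            for child in (c1, c2):
                flip = rng.random(m) < config.mutation_prob
                if flip.any():
                    shifts = rng.integers(1, 3, size=int(flip.sum()))
                    child[flip] = (child[flip] + shifts) % 3
            children.append(c1)
            if len(children) < pop_size:
                children.append(c2)
        pop = np.asarray(children, dtype=np.int8)
        fits = eval_pop(pop)
        top = int(np.argmax(fits))
        history.append(
            FitnessRecord(gen, int(fits[top]), float(fits.mean()), _codes_to_str(pop[top]))
        )
        if int(fits[top]) > best_fit:
            best_fit = int(fits[top])
            best_chrom = _codes_to_str(pop[top])
            stall = 0
        else:
            stall += 1
        if stall >= config.stall_generations:
            break
    return best_chrom, history
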
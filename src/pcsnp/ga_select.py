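"""Genetic algorithms over binary SNP-selection masks.

Two variants share the same machinery — roulette-wheel parent selection,
multi-point crossover, and elitist replacement — and differ only in the
mutation operator:

* ``conventional``: each bit flips independently with probability P_m, so
  the expected selected fraction is preserved and subsets hover around half
  of the candidate features.
* ``modified``: a position chosen for mutation (probability P_m) is
  *replaced* by 1 with probability P_m and by 0 otherwise.  The asymmetry
  breaks the flip symmetry, steering the stationary selected fraction
  toward P_m and giving direct control over subset size.

Fitness is a pluggable ``mask -> [0, 1]`` callable; in the selection
pipeline it is the cross-validated SVM accuracy of the masked feature set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class Individual:
    """A candidate feature subset: a bit mask plus its evaluated fitness."""

    mask: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "Individual":
        return Individual(self.mask.copy(), self.fitness)


@dataclass
class GAConfig:
    """Hyperparameters of a GA run.

    Defaults follow the usual SNP-selection setup: 30 chromosomes,
    crossover rate 0.8, a fixed cap of 10 generations, and two crossover
    points.  ``init_p`` is the probability that a bit starts as 1.
    """

    pop_size: int = 30
    p_crossover: float = 0.8
    p_mutation: float = 0.5
    max_generations: int = 10
    mode: str = "conventional"
    n_crossover_points: int = 2
    init_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for name in ("p_crossover", "p_mutation", "init_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mode not in ("conventional", "modified"):
            raise ValueError(f"mode must be 'conventional' or 'modified', got {self.mode!r}")
        if self.n_crossover_points < 1:
            raise ValueError("n_crossover_points must be >= 1")


@dataclass
class GAResult:
    """Outcome of one GA run: best-ever individual plus convergence log."""

    best: Individual
    history: list = field(default_factory=list)
    n_evaluations: int = 0


def _repair(mask: np.ndarray, rng: np.random.Generator) -> None:
    """Set one random bit of an all-zero mask (fitness needs >= 1 feature)."""
    if not mask.any():
        mask[rng.integers(mask.size)] = True


def init_population(d: int, cfg: GAConfig, rng: np.random.Generator) -> list:
    """pop_size random masks; each bit is 1 with probability ``cfg.init_p``."""
    if d < 1:
        raise ValueError(f"mask length d must be >= 1, got {d}")
    population = []
    for _ in range(cfg.pop_size):
        mask = rng.random(d) < cfg.init_p
        _repair(mask, rng)
        population.append(Individual(mask))
    return population


def roulette_select(population: list, rng: np.random.Generator):
    """Draw two distinct parents with probability proportional to fitness.

    If all fitnesses are equal (including all zero) the draw is uniform.
    """
    fits = np.array(
        [np.nan if ind.fitness is None else ind.fitness for ind in population],
        dtype=float,
    )
    if np.isnan(fits).any():
        raise ValueError("all individuals must be evaluated before selection")
    if (fits < 0).any():
        raise ValueError("fitness values must be non-negative")
    if np.ptp(fits) == 0:
        p = np.full(fits.size, 1.0 / fits.size)
    else:
        p = fits / fits.sum()
    i = int(rng.choice(fits.size, p=p))
    q = p.copy()
    q[i] = 0.0
    if q.sum() == 0:  # the only positive-fitness parent was drawn first
        q = np.full(fits.size, 1.0 / (fits.size - 1))
        q[i] = 0.0
    else:
        q = q / q.sum()
    j = int(rng.choice(fits.size, p=q))
    return population[i], population[j]


def multipoint_crossover(
    a: Individual, b: Individual, cfg: GAConfig, rng: np.random.Generator
):
    """Exchange alternating segments between sorted random cut positions.

    With probability ``cfg.p_crossover`` the parents swap every second
    segment delimited by ``n_crossover_points`` distinct cuts; otherwise the
    children are plain copies.  At each position the children's bits are a
    permutation of the parents' bits, so bit counts are conserved pairwise.
    """
    if a.mask.size != b.mask.size:
        raise ValueError("parent masks must have equal length")
    d = a.mask.size
    child1, child2 = a.mask.copy(), b.mask.copy()
    if rng.random() < cfg.p_crossover and d >= 2:
        k = min(cfg.n_crossover_points, d - 1)
        cuts = np.sort(rng.choice(np.arange(1, d), size=k, replace=False))
        swap = False
        prev = 0
        for cut in list(cuts) + [d]:
            if swap:
                child1[prev:cut] = b.mask[prev:cut]
                child2[prev:cut] = a.mask[prev:cut]
            swap = not swap
            prev = cut
    return Individual(child1), Individual(child2)


def mutate_conventional(
    ind: Individual, p_m: float, rng: np.random.Generator
) -> Individual:
    """Flip each bit independently with probability *p_m* (symmetric)."""
    flips = rng.random(ind.mask.size) < p_m
    return Individual(ind.mask ^ flips)


def mutate_modified(
    ind: Individual, p_m: float, rng: np.random.Generator
) -> Individual:
    """Asymmetric mutation: a mutated position becomes 1 iff r <= p_m.

    Each position is chosen for mutation independently with probability
    *p_m*; a chosen position is overwritten by 1 when a fresh uniform draw r
    satisfies r <= p_m, and by 0 otherwise.  Repeated application drives the
    selected fraction toward the fixed point of
    x -> (1 - p_m) x + p_m * p_m, i.e. toward p_m itself.
    """
    d = ind.mask.size
    chosen = rng.random(d) < p_m
    new_value = rng.random(d) <= p_m
    mask = ind.mask.copy()
    mask[chosen] = new_value[chosen]
    return Individual(mask)


def _elitist_replace(parents: list, offspring: list, pop_size: int) -> list:
    """Merge parents and offspring, keep the fittest pop_size individuals.

    Exact fitness ties are resolved in favour of offspring (stable sort
    with offspring listed first).  This matters whenever the fitness
    plateaus — common once cross-validated accuracy saturates — because a
    parent-wins rule would freeze the population and mask the mutation
    operator's pressure on subset size, which is the whole point of the
    asymmetric variant.  A strictly fitter parent always survives.
    """
    combined = offspring + parents
    combined.sort(key=lambda ind: -ind.fitness)
    return combined[:pop_size]


def evolve(
    d: int,
    cfg: GAConfig,
    fitness: Callable[[np.ndarray], float],
) -> GAResult:
    """Run the GA over masks of length *d* and return the best-ever subset.

    Each generation draws pop_size offspring through roulette selection,
    multi-point crossover, and the configured mutation operator, evaluates
    them, and applies elitist replacement (weaker parents are displaced by
    fitter offspring).  The run stops at the fixed generation cap.  The
    per-generation best/mean fitness log is returned for convergence plots;
    a fitness cache avoids re-evaluating duplicate masks.
    """
    rng = np.random.default_rng(cfg.seed)
    mutate = mutate_modified if cfg.mode == "modified" else mutate_conventional
    cache: dict = {}

    def evaluate(ind: Individual, generation: int) -> None:
        if ind.fitness is not None:
            return
        key = ind.mask.tobytes()
        if key not in cache:
            try:
                value = float(fitness(ind.mask))
            except Exception as exc:
                raise RuntimeError(
                    f"fitness evaluation failed at generation {generation}"
                ) from exc
            cache[key] = value
        ind.fitness = cache[key]

    population = init_population(d, cfg, rng)
    for ind in population:
        evaluate(ind, 0)
    population.sort(key=lambda ind: -ind.fitness)
    history = [
        {
            "generation": 0,
            "best_fitness": population[0].fitness,
            "mean_fitness": float(np.mean([i.fitness for i in population])),
            "best_n_selected": population[0].n_selected,
        }
    ]

    for generation in range(1, cfg.max_generations + 1):
        offspring: list = []
        while len(offspring) < cfg.pop_size:
            pa, pb = roulette_select(population, rng)
            for child in multipoint_crossover(pa, pb, cfg, rng):
                mutant = mutate(child, cfg.p_mutation, rng)
                _repair(mutant.mask, rng)
                offspring.append(mutant)
        offspring = offspring[: cfg.pop_size]
        for ind in offspring:
            evaluate(ind, generation)
        population = _elitist_replace(population, offspring, cfg.pop_size)
        # elitism invariant: the incumbent best fitness can never degrade
        assert population[0].fitness >= history[-1]["best_fitness"]
        history.append(
            {
                "generation": generation,
                "best_fitness": population[0].fitness,
                "mean_fitness": float(np.mean([i.fitness for i in population])),
                "best_n_selected": population[0].n_selected,
            }
        )
    return GAResult(
        best=population[0].copy(), history=history, n_evaluations=len(cache)
    )
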
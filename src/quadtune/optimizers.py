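"""Differential evolution (classic and subpopulation-ranked) and standard PSO.

All optimizers minimize a black-box objective ``f(x) -> float`` over a box
domain, share one population/evaluation contract, and draw every random
number from a single seeded generator in a documented fixed order (per
generation, for each individual in stored order: mutation draws first, then
crossover draws).  That fixed order is what lets the improved algorithm
degenerate bit-for-bit into DE/rand-to-best/1/bin when its subpopulations
are collapsed, which is the main correctness oracle for the implementation.

The improved algorithm ranks individuals by fitness each generation and
splits them into an elite (ELS), a middle (MIS) and an inferior (INS)
subpopulation whose relative sizes shift from 2:5:3 over 4:4:2 to 6:3:1 as
the run progresses.  Elites search near the incumbent with a decaying
mutation factor F1 = alpha1 * u * (1 - g/G)^2; the middle group moves toward
the incumbent with a fixed factor F2 and a slowly decaying factor
F3 = alpha2 + alpha3 * (1 - sqrt(g/G)); inferior individuals are resampled
uniformly inside the bounds as a random restart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Strategy",
    "OptimizerConfig",
    "Individual",
    "Population",
    "SubpopulationPartition",
    "OptimizationResult",
    "initialize_population",
    "stage_partition",
    "stage_ratios",
    "mutation_factors",
    "de_rand_1",
    "de_best_1",
    "de_rand_to_best_1",
    "mutate",
    "crossover_binomial",
    "clip_to_bounds",
    "select_greedy",
    "inertia_weight",
    "run_de",
    "run_pso",
    "run",
]

Objective = Callable[[np.ndarray], float]


class Strategy(str, Enum):
    DE_RAND_1 = "DE/rand/1/bin"
    DE_BEST_1 = "DE/best/1/bin"
    DE_RAND_TO_BEST_1 = "DE/rand-to-best/1/bin"
    DE_IMPROVED = "DE-i"
    PSO = "PSO"


#: stage -> (elite, middle, inferior) population fractions
STAGE_RATIOS = {
    "early": (0.2, 0.5, 0.3),
    "middle": (0.4, 0.4, 0.2),
    "late": (0.6, 0.3, 0.1),
}


@dataclass
class OptimizerConfig:
    """All algorithm constants for one run.

    Defaults follow the tuning study this package reproduces: for the
    improved DE alpha1 = 1, F2 = 0.4, alpha2 = alpha3 = 0.3, CR = 0.75;
    for PSO an inertia weight decreasing linearly from 0.9 to 0.4 with
    c1 = c2 = 2.  The classic-DE factor F and the rand-to-best weight
    lambda default to the conventional mid-range 0.5.
    """

    D: int
    lower: "np.ndarray | float"
    upper: "np.ndarray | float"
    strategy: Strategy = Strategy.DE_IMPROVED
    N: int = 20
    G: int = 25
    F: float = 0.5
    CR: float = 0.75
    lambda_rtb: float = 0.5
    alpha1: float = 1.0
    alpha2: float = 0.3
    alpha3: float = 0.3
    F2: float = 0.4
    pso_w_start: float = 0.9
    pso_w_end: float = 0.4
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_vmax_frac: float = 0.2
    seed: int = 0
    stage_ratio_override: "tuple[float, float, float] | None" = None

    def __post_init__(self) -> None:
        self.strategy = Strategy(self.strategy)
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.D,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.D,)).copy()
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound in some coordinate")
        if self.N < 4:
            raise ValueError("population size must be at least 4")
        if self.strategy is Strategy.DE_IMPROVED and self.N < 5:
            raise ValueError("improved DE requires a population of at least 5")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must lie in [0, 1]")


@dataclass
class Individual:
    x: np.ndarray
    fitness: float


@dataclass
class Population:
    """N candidate vectors with fitness, stored as arrays."""

    x: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    generation: int = 0

    @property
    def size(self) -> int:
        return self.x.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def members(self) -> list[Individual]:
        return [Individual(self.x[i].copy(), float(self.fitness[i])) for i in range(self.size)]


@dataclass
class SubpopulationPartition:
    """Disjoint rank-based index sets: elite holds the best-ranked members."""

    elite: np.ndarray
    middle: np.ndarray
    inferior: np.ndarray
    stage: str

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.elite), len(self.middle), len(self.inferior)


@dataclass
class OptimizationResult:
    best_x: np.ndarray
    best_fitness: float
    convergence: np.ndarray  # length G + 1, best-so-far
    evaluations: int
    strategy: Strategy = Strategy.DE_IMPROVED


def initialize_population(config: OptimizerConfig, rng: np.random.Generator,
                          objective: Objective | None = None) -> Population:
    """Uniform initialization x = lb + u (ub - lb), coordinate-wise."""
    u = rng.random((config.N, config.D))
    x = config.lower + u * (config.upper - config.lower)
    if objective is not None:
        fit = np.array([objective(xi) for xi in x])
    else:
        fit = np.full(config.N, np.nan)
    return Population(x=x, fitness=fit, generation=0)


def _stage(g: int, G: int) -> str:
    if g <= G / 3:
        return "early"
    if g <= 2 * G / 3:
        return "middle"
    return "late"


def stage_ratios(g: int, G: int) -> tuple[float, float, float]:
    return STAGE_RATIOS[_stage(g, G)]


def _partition_sizes(n: int, ratios: tuple[float, float, float],
                     repair_empty: bool) -> tuple[int, int, int]:
    ne = int(round(ratios[0] * n))
    ni = int(round(ratios[2] * n))
    nm = n - ne - ni
    sizes = [ne, nm, ni]
    if repair_empty and n >= 10:
        while min(sizes) == 0:
            sizes[int(np.argmax(sizes))] -= 1
            sizes[int(np.argmin(sizes))] += 1
    return sizes[0], sizes[1], sizes[2]


def stage_partition(
    population: Population,
    g: int,
    G: int,
    ratio_override: "tuple[float, float, float] | None" = None,
) -> SubpopulationPartition:
    """Rank ascending by fitness and split into ELS/MIS/INS for the stage."""
    n = population.size
    stage = _stage(g, G)
    if ratio_override is not None:
        total = sum(ratio_override)
        ratios = tuple(r / total for r in ratio_override)
        repair = False
    else:
        ratios = STAGE_RATIOS[stage]
        repair = True
    ne, nm, ni = _partition_sizes(n, ratios, repair)
    order = np.argsort(population.fitness, kind="stable")
    return SubpopulationPartition(
        elite=order[:ne], middle=order[ne:ne + nm], inferior=order[ne + nm:], stage=stage
    )


def mutation_factors(g: int, G: int, config: OptimizerConfig,
                     rng: np.random.Generator) -> tuple[float, float]:
    """Adaptive factors: F1 (one fresh uniform draw) and deterministic F3."""
    if G == 0:
        raise ValueError("G must be positive")
    ratio = g / G
    f1 = config.alpha1 * rng.random() * (1.0 - ratio) ** 2
    f3 = config.alpha2 + config.alpha3 * (1.0 - math.sqrt(ratio))
    return f1, f3


def de_rand_1(x_r1: np.ndarray, x_r2: np.ndarray, x_r3: np.ndarray, F: float) -> np.ndarray:
    return x_r1 + F * (x_r2 - x_r3)


def de_best_1(x_best: np.ndarray, x_r1: np.ndarray, x_r2: np.ndarray, F: float) -> np.ndarray:
    return x_best + F * (x_r1 - x_r2)


def de_rand_to_best_1(x_i: np.ndarray, x_best: np.ndarray, x_r1: np.ndarray,
                      x_r2: np.ndarray, lam: float, F: float) -> np.ndarray:
    return x_i + lam * (x_best - x_i) + F * (x_r1 - x_r2)


def _sample_distinct(rng: np.random.Generator, n: int, k: int,
                     exclude: set[int]) -> list[int]:
    if n - len(exclude) < k:
        raise ValueError(f"population of {n} too small to draw {k} distinct donors")
    picked: list[int] = []
    taken = set(exclude)
    while len(picked) < k:
        j = int(rng.integers(n))
        if j not in taken:
            picked.append(j)
            taken.add(j)
    return picked


def mutate(
    population: Population,
    i: int,
    config: OptimizerConfig,
    rng: np.random.Generator,
    g: int = 0,
    best_index: int | None = None,
    partition: SubpopulationPartition | None = None,
) -> np.ndarray:
    """Produce the mutant vector for individual ``i`` under the configured
    strategy.  For the improved strategy, ``partition`` decides the rule."""
    x = population.x
    n = population.size
    best = population.best_index if best_index is None else best_index
    strat = config.strategy

    if strat is Strategy.DE_RAND_1:
        r1, r2, r3 = _sample_distinct(rng, n, 3, {i})
        return de_rand_1(x[r1], x[r2], x[r3], config.F)
    if strat is Strategy.DE_BEST_1:
        r1, r2 = _sample_distinct(rng, n, 2, {i})
        return de_best_1(x[best], x[r1], x[r2], config.F)
    if strat is Strategy.DE_RAND_TO_BEST_1:
        r1, r2 = _sample_distinct(rng, n, 2, {i})
        return de_rand_to_best_1(x[i], x[best], x[r1], x[r2], config.lambda_rtb, config.F)
    if strat is Strategy.DE_IMPROVED:
        if partition is None:
            partition = stage_partition(population, g, config.G, config.stage_ratio_override)
        if i in partition.inferior:
            u = rng.random(config.D)
            return config.lower + u * (config.upper - config.lower)
        if i in partition.elite:
            f1, _ = mutation_factors(g, config.G, config, rng)
            r1, r2 = _sample_distinct(rng, n, 2, {i, best})
            return de_best_1(x[best], x[r1], x[r2], f1)
        f3 = config.alpha2 + config.alpha3 * (1.0 - math.sqrt(g / config.G))
        r1, r2 = _sample_distinct(rng, n, 2, {i})
        return de_rand_to_best_1(x[i], x[best], x[r1], x[r2], config.F2, f3)
    raise ValueError(f"{strat} is not a DE mutation strategy")


def crossover_binomial(target: np.ndarray, mutant: np.ndarray, CR: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover: mutant coordinate where randb(j) <= CR or j is the
    forced index, so at least one coordinate always comes from the mutant."""
    d = len(target)
    if len(mutant) != d:
        raise ValueError("target and mutant must have equal length")
    randb = rng.random(d)
    forced = int(rng.integers(d))
    take = (randb <= CR)
    take[forced] = True
    return np.where(take, mutant, target)


def clip_to_bounds(v: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return np.clip(v, lower, upper)


def select_greedy(target: Individual, trial: Individual) -> Individual:
    """Greedy one-to-one selection: the trial survives iff strictly better.

    A non-finite fitness on one side loses automatically; non-finite on both
    sides is an error.
    """
    tf, uf = target.fitness, trial.fitness
    if not math.isfinite(tf) and not math.isfinite(uf):
        raise ValueError("both candidates have non-finite fitness")
    if not math.isfinite(uf):
        return target
    if not math.isfinite(tf):
        return trial
    return trial if uf < tf else target


GenerationCallback = Callable[[int, np.ndarray, np.ndarray], None]


def run_de(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    callback: GenerationCallback | None = None,
) -> OptimizationResult:
    """Run one of the DE variants for G generations.

    Selection is synchronous: all trial vectors of a generation are built
    from the surviving population of the previous generation, and the
    incumbent best is refreshed once per generation after selection.
    """
    if config.strategy is Strategy.PSO:
        raise ValueError("use run_pso for the PSO strategy")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def _eval(x: np.ndarray, g: int) -> float:
        try:
            return float(objective(x))
        except Exception as exc:
            raise RuntimeError(f"objective evaluation failed at generation {g}") from exc

    u0 = rng.random((config.N, config.D))
    x = config.lower + u0 * (config.upper - config.lower)
    fit = np.array([_eval(xi, 0) for xi in x])
    evals = config.N
    curve = [float(np.min(fit))]
    if callback is not None:
        callback(0, x.copy(), fit.copy())

    improved = config.strategy is Strategy.DE_IMPROVED
    for g in range(config.G):
        pop = Population(x=x, fitness=fit, generation=g)
        best = pop.best_index
        partition = None
        in_elite = in_inferior = None
        if improved:
            partition = stage_partition(pop, g, config.G, config.stage_ratio_override)
            in_elite = np.zeros(config.N, dtype=bool)
            in_elite[partition.elite] = True
            in_inferior = np.zeros(config.N, dtype=bool)
            in_inferior[partition.inferior] = True
            f3 = config.alpha2 + config.alpha3 * (1.0 - math.sqrt(g / config.G))

        new_x = np.empty_like(x)
        new_f = np.empty_like(fit)
        for i in range(config.N):
            if not improved:
                if config.strategy is Strategy.DE_RAND_1:
                    r1, r2, r3 = _sample_distinct(rng, config.N, 3, {i})
                    v = de_rand_1(x[r1], x[r2], x[r3], config.F)
                elif config.strategy is Strategy.DE_BEST_1:
                    r1, r2 = _sample_distinct(rng, config.N, 2, {i})
                    v = de_best_1(x[best], x[r1], x[r2], config.F)
                else:
                    r1, r2 = _sample_distinct(rng, config.N, 2, {i})
                    v = de_rand_to_best_1(x[i], x[best], x[r1], x[r2],
                                          config.lambda_rtb, config.F)
            elif in_inferior[i]:
                u = rng.random(config.D)
                v = config.lower + u * (config.upper - config.lower)
            elif in_elite[i]:
                f1 = config.alpha1 * rng.random() * (1.0 - g / config.G) ** 2
                r1, r2 = _sample_distinct(rng, config.N, 2, {i, best})
                v = de_best_1(x[best], x[r1], x[r2], f1)
            else:
                r1, r2 = _sample_distinct(rng, config.N, 2, {i})
                v = de_rand_to_best_1(x[i], x[best], x[r1], x[r2], config.F2, f3)

            u_vec = crossover_binomial(x[i], v, config.CR, rng)
            u_vec = clip_to_bounds(u_vec, config.lower, config.upper)
            fu = _eval(u_vec, g)
            evals += 1
            if math.isfinite(fu) and (not math.isfinite(fit[i]) or fu < fit[i]):
                new_x[i], new_f[i] = u_vec, fu
            else:
                new_x[i], new_f[i] = x[i], fit[i]

        x, fit = new_x, new_f
        curve.append(min(curve[-1], float(np.min(fit))))
        if callback is not None:
            callback(g + 1, x.copy(), fit.copy())

    best = int(np.argmin(fit))
    return OptimizationResult(
        best_x=x[best].copy(),
        best_fitness=float(fit[best]),
        convergence=np.array(curve),
        evaluations=evals,
        strategy=config.strategy,
    )


def inertia_weight(g: int, G: int, w_start: float = 0.9, w_end: float = 0.4) -> float:
    """Linearly decreasing inertia weight: w_start at g = 0, w_end at g = G."""
    return w_start + (w_end - w_start) * (g / G)


def run_pso(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    callback: GenerationCallback | None = None,
) -> OptimizationResult:
    """Standard global-best PSO with linearly decreasing inertia weight."""
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def _eval(x: np.ndarray, g: int) -> float:
        try:
            return float(objective(x))
        except Exception as exc:
            raise RuntimeError(f"objective evaluation failed at generation {g}") from exc

    span = config.upper - config.lower
    vmax = config.pso_vmax_frac * span
    u0 = rng.random((config.N, config.D))
    x = config.lower + u0 * span
    v = np.zeros_like(x)
    fit = np.array([_eval(xi, 0) for xi in x])
    evals = config.N
    pbest_x, pbest_f = x.copy(), fit.copy()
    gi = int(np.argmin(fit))
    gbest_x, gbest_f = x[gi].copy(), float(fit[gi])
    curve = [gbest_f]
    if callback is not None:
        callback(0, x.copy(), fit.copy())

    for g in range(config.G):
        w = inertia_weight(g, config.G, config.pso_w_start, config.pso_w_end)
        r1 = rng.random((config.N, config.D))
        r2 = rng.random((config.N, config.D))
        v = (w * v + config.pso_c1 * r1 * (pbest_x - x)
             + config.pso_c2 * r2 * (gbest_x - x))
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, config.lower, config.upper)
        fit = np.array([_eval(xi, g) for xi in x])
        evals += config.N
        better = fit < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = fit[better]
        gi = int(np.argmin(pbest_f))
        if pbest_f[gi] < gbest_f:
            gbest_x, gbest_f = pbest_x[gi].copy(), float(pbest_f[gi])
        curve.append(gbest_f)
        if callback is not None:
            callback(g + 1, x.copy(), fit.copy())

    return OptimizationResult(
        best_x=gbest_x,
        best_fitness=gbest_f,
        convergence=np.array(curve),
        evaluations=evals,
        strategy=Strategy.PSO,
    )


def run(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    callback: GenerationCallback | None = None,
) -> OptimizationResult:
    """Dispatch to run_pso or run_de based on the configured strategy."""
    if config.strategy is Strategy.PSO:
        return run_pso(objective, config, rng, callback)
    return run_de(objective, config, rng, callback)
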
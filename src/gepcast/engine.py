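"""Fitness evaluation and the generational GEP evolution loop.

Three fitness modes are supported, all formulated as maximization:

* ``mse`` (default): negated mean squared error over the fitness cases.
* ``relative``: ``sum_j (M - |C_ij - T_j| / |T_j|)`` — selection-range
  fitness for relative-error problems.
* ``absolute``: ``sum_j (M - |C_ij - T_j|)`` for absolute-error
  problems.

``M`` is the *selection range*, a constant from which per-case error is
subtracted so that perfect predictions attain ``Ct * M``.  Individuals
whose expression evaluates to a non-finite value on any case receive a
``-inf`` sentinel and are eliminated by selection.

Each generation applies, population-wide and in a fixed order:
truncation selection (worst quarter replaced by the best quarter),
point mutation, head inversion, IS/RIS/gene transposition, and
one-point/two-point/gene recombination over a random pairing.  The
best-ever individual is re-inserted every generation (elitism), so the
best-fitness trace is monotonically non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .karva import Chromosome, GeneArchitecture, evaluate_chromosome, random_chromosome
from .operators import (
    OperatorRates,
    invert,
    mutate,
    recombine_gene,
    recombine_one_point,
    recombine_two_point,
    select_replicate,
    transpose_gene,
    transpose_is,
    transpose_ris,
)

__all__ = [
    "WORST_FITNESS",
    "FitnessContext",
    "EngineConfig",
    "EvolutionResult",
    "fitness_cases",
    "fitness_mse",
    "evolve",
]

#: Sentinel assigned to individuals with non-finite predictions.
WORST_FITNESS = float("-inf")


@dataclass
class FitnessContext:
    """Targets and per-case features for fitness evaluation.

    ``case_features`` maps each terminal symbol to an array of its
    values over the fitness cases; ``targets`` holds the corresponding
    target values ``T_j``.
    """

    targets: np.ndarray
    case_features: Mapping[str, np.ndarray]
    selection_range: float = 100.0
    mode: str = "mse"

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.case_features = {
            k: np.asarray(v, dtype=float) for k, v in self.case_features.items()
        }
        if self.targets.size < 1:
            raise ValueError("at least one fitness case required")
        for k, v in self.case_features.items():
            if v.shape != self.targets.shape:
                raise ValueError(f"feature {k!r} length mismatch with targets")
        if self.mode not in ("relative", "absolute", "mse"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")
        if self.mode == "relative" and np.any(self.targets == 0):
            raise ValueError("relative-error fitness undefined for zero targets")

    @property
    def n_cases(self) -> int:
        return int(self.targets.size)


def _predictions(individual: Chromosome, context: FitnessContext) -> np.ndarray:
    return np.asarray(
        evaluate_chromosome(individual, context.case_features), dtype=float
    )


def fitness_cases(individual: Chromosome, context: FitnessContext) -> float:
    """Selection-range fitness (relative or absolute mode)."""
    preds = _predictions(individual, context)
    if not np.all(np.isfinite(preds)):
        return WORST_FITNESS
    with np.errstate(all="ignore"):
        err = np.abs(preds - context.targets)
        if context.mode == "relative":
            err = err / np.abs(context.targets)
        return float(np.sum(context.selection_range - err))


def fitness_mse(individual: Chromosome, context: FitnessContext) -> float:
    """Negated mean squared error (larger is fitter; 0 is perfect)."""
    preds = _predictions(individual, context)
    if not np.all(np.isfinite(preds)):
        return WORST_FITNESS
    with np.errstate(all="ignore"):
        value = -float(np.mean((preds - context.targets) ** 2))
    return value if np.isfinite(value) else WORST_FITNESS


def _fitness(individual: Chromosome, context: FitnessContext) -> float:
    if context.mode == "mse":
        return fitness_mse(individual, context)
    return fitness_cases(individual, context)


@dataclass
class EngineConfig:
    """Run parameters for :func:`evolve`.

    Defaults follow the published configuration: population 30, 1000
    generations, MSE fitness, the per-operator rates of
    :class:`~gepcast.operators.OperatorRates`, elitism on.  The
    convergence plateau (stop when the best fitness improves by less
    than ``plateau_tol`` for ``plateau_patience`` consecutive
    generations) is an optional safeguard, off by default.
    """

    population_size: int = 30
    max_generations: int = 1000
    rates: OperatorRates = field(default_factory=OperatorRates)
    elitism: bool = True
    rng_seed: int = 0
    plateau_stop: bool = False
    plateau_tol: float = 1e-8
    plateau_patience: int = 50

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class EvolutionResult:
    best: Chromosome
    best_fitness: float
    history: list[float]

    @property
    def generations(self) -> int:
        return len(self.history)


def _recombination_pass(population, rng, prob, operator):
    """Pair the population at random; each pair crosses with ``prob``."""
    idx = rng.permutation(len(population))
    out = list(population)
    for k in range(len(idx) // 2):
        i, j = int(idx[2 * k]), int(idx[2 * k + 1])
        if rng.random() < prob:
            out[i], out[j] = operator(out[i], out[j], rng)
    return out


def evolve(
    architecture: GeneArchitecture,
    context: FitnessContext,
    config: EngineConfig | None = None,
) -> EvolutionResult:
    """Run the generational loop and return the best-ever individual
    with its per-generation best-fitness trace."""
    config = config or EngineConfig()
    rng = np.random.default_rng(config.rng_seed)
    rates = config.rates
    pop = [random_chromosome(architecture, rng) for _ in range(config.population_size)]

    best: Chromosome | None = None
    best_fit = WORST_FITNESS
    history: list[float] = []
    stall = 0

    for gen in range(config.max_generations):
        fits = [_fitness(ind, context) for ind in pop]
        gen_best = max(range(len(pop)), key=lambda i: fits[i])
        if fits[gen_best] > best_fit or best is None:
            improvement = fits[gen_best] - best_fit
            best, best_fit = pop[gen_best], fits[gen_best]
        else:
            improvement = 0.0
        history.append(best_fit)

        if config.plateau_stop:
            stall = stall + 1 if improvement < config.plateau_tol else 0
            if stall >= config.plateau_patience:
                break
        if gen == config.max_generations - 1:
            break

        pop = select_replicate(pop, fits)
        pop = [mutate(c, rates.mutation_p, rng) for c in pop]
        pop = [invert(c, rng) if rng.random() < rates.inversion_p else c for c in pop]
        pop = [transpose_is(c, rng) if rng.random() < rates.is_p else c for c in pop]
        pop = [transpose_ris(c, rng) if rng.random() < rates.ris_p else c for c in pop]
        pop = [
            transpose_gene(c, rng) if rng.random() < rates.gene_transpose_p else c
            for c in pop
        ]
        pop = _recombination_pass(pop, rng, rates.one_point_p, recombine_one_point)
        pop = _recombination_pass(pop, rng, rates.two_point_p, recombine_two_point)
        pop = _recombination_pass(pop, rng, rates.gene_recomb_p, recombine_gene)
        if config.elitism and best is not None:
            pop[-1] = best

    assert best is not None
    return EvolutionResult(best=best, best_fitness=best_fit, history=history)
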
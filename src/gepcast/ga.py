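"""Hyperparameter search: binary codec, real-coded GA, and CV grid search.

The genetic algorithm here is the parameter optimizer that surrounds
the symbolic-regression engine: candidate hyperparameter vectors live
in a bounding box, truncation selection replaces the worst quarter with
the best quarter, crossover blends non-repeating pairs convexly, and
mutation contracts a coordinate toward one of its bounds under a random
binary mask.  Convergence is declared when the best fitness changes by
less than a preset tolerance between consecutive generations.

The binary codec maps length-``L`` bit strings onto a uniform lattice
over ``[x_min, x_max]`` with resolution ``(x_max - x_min) / (2^L - 1)``;
the all-zeros code decodes to ``x_min`` and all-ones to ``x_max``.

``grid_search_cv`` is the k-fold cross-validation alternative used to
pick the support-vector cost ``C`` and RBF width ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "BinaryCodec",
    "GAConfig",
    "GAResult",
    "GridSearchResult",
    "codec_precision",
    "decode_bits",
    "crossover_real",
    "crossover_int",
    "mutate_bounded",
    "ga_optimize",
    "grid_search_cv",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

#: Default log-spaced hyperparameter grids: C in 2^-2..2^8, gamma in
#: 2^-10..2^2.
DEFAULT_C_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-2, 9))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-10, 3))


@dataclass(frozen=True)
class BinaryCodec:
    """Fixed-point binary encoding of a bounded real parameter."""

    x_min: float
    x_max: float
    n_bits: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")

    @property
    def precision(self) -> float:
        return codec_precision(self)


def codec_precision(codec: BinaryCodec) -> float:
    """Lattice step ``(x_max - x_min) / (2^L - 1)``."""
    return (codec.x_max - codec.x_min) / (2**codec.n_bits - 1)


def decode_bits(bits: str | Sequence[int], codec: BinaryCodec) -> float:
    """Decode a bit string (most significant bit first) to its real
    value ``x_min + value * precision``."""
    if isinstance(bits, str):
        bit_list = [int(c) for c in bits]
    else:
        bit_list = [int(b) for b in bits]
    if len(bit_list) != codec.n_bits:
        raise ValueError(f"expected {codec.n_bits} bits, got {len(bit_list)}")
    if any(b not in (0, 1) for b in bit_list):
        raise ValueError("bits must be 0 or 1")
    value = 0
    for b in bit_list:
        value = (value << 1) | b
    return codec.x_min + value * codec_precision(codec)


def crossover_real(
    x_i: np.ndarray,
    x_j: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    a: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convex blend: ``x_i' = (1-a) x_i + a x_j`` and symmetrically for
    ``x_j'``, with ``a ~ Uniform(0, 1)``.  Convexity keeps children in
    any box containing the parents."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("parents must share dimensionality")
    if a is None:
        a = float(rng.random())
    return (1 - a) * x_i + a * x_j, a * x_i + (1 - a) * x_j


def crossover_int(
    x_i: np.ndarray,
    x_j: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    a: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer variant of :func:`crossover_real`: the blend is rounded
    to the nearest integer."""
    ci, cj = crossover_real(x_i, x_j, rng, a=a)
    return np.round(ci), np.round(cj)


def mutate_bounded(
    x: np.ndarray,
    mask_bits: Sequence[int],
    b: float,
    bounds: Sequence[tuple[float, float]],
    *,
    literal_upper_branch: bool = False,
) -> np.ndarray:
    """Masked bounded mutation.

    For each coordinate, a mask bit of 0 contracts toward the lower
    bound, ``x' = x - (x - x_min) b``; a mask bit of 1 moves toward the
    upper bound, ``x' = x + (x_max - x) b``.  With ``b in [0, 1]`` the
    mutant never leaves the box.  ``literal_upper_branch`` switches the
    1-branch to ``x - (x_max - x) b``, which does not guarantee bound
    containment and is provided for comparison only.
    """
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask_bits, dtype=int)
    lo = np.array([bd[0] for bd in bounds], dtype=float)
    hi = np.array([bd[1] for bd in bounds], dtype=float)
    if mask.shape != x.shape:
        raise ValueError("mask length must equal dimension")
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    down = x - (x - lo) * b
    if literal_upper_branch:
        up = x - (hi - x) * b
    else:
        up = x + (hi - x) * b
    return np.where(mask == 0, down, up)


@dataclass
class GAConfig:
    """Real-coded GA parameters: crossover rate 0.9, mutation rate 0.1.

    ``tolerance`` is the convergence threshold on the change of the
    best fitness between consecutive generations; 0 disables early
    stopping and the loop runs the full ``max_generations``.
    """

    population_size: int = 30
    crossover_p: float = 0.9
    mutation_p: float = 0.1
    tolerance: float = 0.0
    max_generations: int = 100
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class GAResult:
    best: np.ndarray
    best_fitness: float
    trace: list[float]


def ga_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> GAResult:
    """Maximize ``objective`` over a box with the real-coded GA.

    Per generation: evaluate, record the running best, test
    ``|fitmax_{k+1} - fitmax_k| < tolerance``, then truncation-select,
    cross non-repeating pairs with probability ``crossover_p`` and
    mutate individuals with probability ``mutation_p``.  The best-ever
    individual is re-inserted each generation, so the returned trace is
    non-decreasing.
    """
    config = config or GAConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy hi > lo")
    n, d = config.population_size, len(bounds)
    pop = rng.uniform(lo, hi, size=(n, d))
    if config.integer_valued:
        pop = np.round(pop)
    cross = crossover_int if config.integer_valued else crossover_real

    best_x: np.ndarray | None = None
    best_f = -np.inf
    trace: list[float] = []

    for gen in range(config.max_generations):
        fits = np.array([objective(ind) for ind in pop])
        k = int(np.argmax(fits))
        if best_x is None or fits[k] > best_f:
            best_x, best_f = pop[k].copy(), float(fits[k])
        trace.append(best_f)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < config.tolerance:
            break
        if gen == config.max_generations - 1:
            break

        # truncation selection: worst quarter replaced by best quarter
        order = np.argsort(-fits, kind="stable")
        pop = pop[order]
        q = n // 4
        if q:
            pop[-q:] = pop[:q]

        # non-repeating pairwise crossover at rate Pc
        idx = rng.permutation(n)
        for p in range(n // 2):
            i, j = int(idx[2 * p]), int(idx[2 * p + 1])
            if rng.random() < config.crossover_p:
                pop[i], pop[j] = cross(pop[i], pop[j], rng)

        # masked bounded mutation at rate Pm
        for i in range(n):
            if rng.random() < config.mutation_p:
                mask = rng.integers(0, 2, size=d)
                b = float(rng.random())
                pop[i] = mutate_bounded(pop[i], mask, b, bounds)
                if config.integer_valued:
                    pop[i] = np.round(pop[i])

        pop[-1] = best_x  # elitism

    assert best_x is not None
    return GAResult(best=best_x, best_fitness=best_f, trace=trace)


@dataclass
class GridSearchResult:
    best_c: float
    best_gamma: float
    best_score: float
    table: list[tuple[float, float, float]]


def grid_search_cv(
    features: np.ndarray,
    targets: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int | None = 0,
    epsilon: float = 0.1,
    chronological: bool = False,
) -> GridSearchResult:
    """Exhaustive (C, gamma) grid search by k-fold cross-validated MSE
    for an RBF support-vector regressor.

    Folds are a seeded random partition by default; with
    ``chronological=True`` contiguous blocks in row order are used
    instead (for time-indexed data).  Ties are broken toward the
    smaller ``C``, then the smaller ``gamma``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if n_folds < 2 or n_folds > len(y):
        raise ValueError("need 2 <= n_folds <= n_samples")
    if chronological:
        splitter = KFold(n_splits=n_folds, shuffle=False)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))

    table: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None
    for c in sorted(set(float(v) for v in c_grid)):
        for g in sorted(set(float(v) for v in gamma_grid)):
            fold_mse = []
            for tr, te in splits:
                model = SVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
                fold_mse.append(float(np.mean((pred - y[te]) ** 2)))
            score = float(np.mean(fold_mse))
            table.append((c, g, score))
            if best is None or score < best[2]:
                best = (c, g, score)
    assert best is not None
    return GridSearchResult(
        best_c=best[0], best_gamma=best[1], best_score=best[2], table=table
    )
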
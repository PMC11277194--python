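"""Genetic operators over K-expression chromosomes.

All operators map valid chromosomes to valid chromosomes: mutation is
domain-aware (head symbols may become functions or terminals, tail
symbols only terminals), insertion-sequence transposition shifts and
truncates within the head so tails are never touched, and recombination
exchanges symbols at identical positions, which preserves the head/tail
split automatically.

Deterministic variants of the random draws are exposed through keyword
arguments (``point=``, ``index=``, ...) so unit tests can pin a
particular outcome; normal callers pass only an ``rng``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .karva import Chromosome

__all__ = [
    "OperatorRates",
    "select_replicate",
    "mutate",
    "invert",
    "transpose_is",
    "transpose_ris",
    "transpose_gene",
    "recombine_one_point",
    "recombine_two_point",
    "recombine_gene",
]

# IS/RIS transposons are "short sequences": lengths drawn from this pool.
_TRANSPOSON_LENGTHS = (1, 2, 3)


@dataclass
class OperatorRates:
    """Per-operator application probabilities (defaults follow the
    published hybrid-run configuration)."""

    mutation_p: float = 0.044
    inversion_p: float = 0.1
    is_p: float = 0.1
    ris_p: float = 0.1
    gene_transpose_p: float = 0.1
    one_point_p: float = 0.3
    two_point_p: float = 0.3
    gene_recomb_p: float = 0.1

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")


def select_replicate(population: list, fitnesses: list[float]) -> list:
    """Truncation selection: sort by fitness descending (stable, so ties
    keep insertion order) and replace the worst quarter with copies of
    the best quarter.  Population size is unchanged; for sizes not
    divisible by 4, ``floor(N/4)`` individuals are replaced."""
    if not population:
        raise ValueError("empty population")
    if len(population) != len(fitnesses):
        raise ValueError("population and fitnesses differ in length")
    order = sorted(range(len(population)), key=lambda i: -fitnesses[i])
    ranked = [population[i] for i in order]
    q = len(population) // 4
    if q:
        ranked[-q:] = ranked[:q]
    return ranked


def mutate(
    chromosome: Chromosome, mutation_p: float, rng: np.random.Generator
) -> Chromosome:
    """Point mutation: each symbol independently replaced with
    probability ``mutation_p``; head positions draw from functions and
    terminals, tail positions from terminals only."""
    arch = chromosome.architecture
    head_pool = arch.head_symbols
    term_pool = arch.terminal_set
    genes = []
    for gene in chromosome.genes:
        new = list(gene)
        for i in range(len(new)):
            if rng.random() < mutation_p:
                pool = head_pool if i < arch.head_len else term_pool
                new[i] = pool[rng.integers(len(pool))]
        genes.append(tuple(new))
    return Chromosome(tuple(genes), arch)


def invert(
    chromosome: Chromosome,
    rng: np.random.Generator | None = None,
    *,
    gene_index: int | None = None,
    span: tuple[int, int] | None = None,
) -> Chromosome:
    """Reverse a random contiguous segment inside one gene's head.

    The head admits both functions and terminals at every position, so
    a reversal within the head always stays valid; tails are never
    touched.
    """
    arch = chromosome.architecture
    h = arch.head_len
    if gene_index is None:
        gene_index = int(rng.integers(arch.gene_count))
    if span is None:
        i = int(rng.integers(h))
        j = int(rng.integers(h)) + 1
        if j <= i:
            i, j = j - 1, i + 1
        span = (i, j)
    lo, hi = span
    if not (0 <= lo < hi <= h):
        raise ValueError(f"span {span} outside head [0, {h})")
    gene = list(chromosome.genes[gene_index])
    gene[lo:hi] = gene[lo:hi][::-1]
    genes = list(chromosome.genes)
    genes[gene_index] = tuple(gene)
    return Chromosome(tuple(genes), arch)


def _insert_into_head(
    chromosome: Chromosome, gene_index: int, position: int, segment: tuple[str, ...]
) -> Chromosome:
    """Insert ``segment`` at a head position, shift the head right and
    truncate at the head boundary; tail unchanged."""
    arch = chromosome.architecture
    h = arch.head_len
    gene = chromosome.genes[gene_index]
    head = list(gene[:h])
    new_head = (head[:position] + list(segment) + head[position:])[:h]
    genes = list(chromosome.genes)
    genes[gene_index] = tuple(new_head) + gene[h:]
    return Chromosome(tuple(genes), arch)


def _random_segment(
    chromosome: Chromosome, rng: np.random.Generator, start: int | None = None
) -> tuple[str, ...]:
    arch = chromosome.architecture
    flat = [s for g in chromosome.genes for s in g]
    if start is None:
        start = int(rng.integers(len(flat)))
    length = _TRANSPOSON_LENGTHS[rng.integers(len(_TRANSPOSON_LENGTHS))]
    return tuple(flat[start : start + length])


def transpose_is(
    chromosome: Chromosome, rng: np.random.Generator
) -> Chromosome:
    """Insertion-sequence transposition: copy a short segment (any
    starting symbol) into a head position other than the root."""
    arch = chromosome.architecture
    if arch.head_len < 2:
        return chromosome  # no non-root head position exists
    segment = _random_segment(chromosome, rng)
    target = int(rng.integers(arch.gene_count))
    position = 1 + int(rng.integers(arch.head_len - 1))
    return _insert_into_head(chromosome, target, position, segment)


def transpose_ris(
    chromosome: Chromosome, rng: np.random.Generator
) -> Chromosome:
    """Root insertion-sequence transposition: like IS, but the segment
    must start with a function symbol and is inserted at the gene root.
    If no function symbol lies at or after the chosen scan point, the
    operation is a no-op."""
    arch = chromosome.architecture
    functions = arch.function_set
    source = int(rng.integers(arch.gene_count))
    gene = chromosome.genes[source]
    scan_from = int(rng.integers(arch.head_len))
    start = next(
        (i for i in range(scan_from, arch.head_len) if gene[i] in functions), None
    )
    if start is None:
        return chromosome
    length = _TRANSPOSON_LENGTHS[rng.integers(len(_TRANSPOSON_LENGTHS))]
    segment = gene[start : start + length]
    target = int(rng.integers(arch.gene_count))
    return _insert_into_head(chromosome, target, 0, segment)


def transpose_gene(
    chromosome: Chromosome,
    rng: np.random.Generator | None = None,
    *,
    index: int | None = None,
) -> Chromosome:
    """Gene transposition: a randomly chosen gene moves to the front of
    the chromosome; the others shift right preserving order."""
    arch = chromosome.architecture
    if index is None:
        index = int(rng.integers(arch.gene_count))
    genes = list(chromosome.genes)
    gene = genes.pop(index)
    return Chromosome(tuple([gene] + genes), arch)


def _flatten(chromosome: Chromosome) -> list[str]:
    return [s for g in chromosome.genes for s in g]


def _rebuild(symbols: list[str], arch) -> Chromosome:
    n = arch.gene_len
    genes = tuple(tuple(symbols[i * n : (i + 1) * n]) for i in range(arch.gene_count))
    return Chromosome(genes, arch)


def _check_same_arch(a: Chromosome, b: Chromosome) -> None:
    if a.architecture is not b.architecture and (
        a.architecture.gene_len != b.architecture.gene_len
        or a.architecture.gene_count != b.architecture.gene_count
        or a.architecture.head_len != b.architecture.head_len
    ):
        raise ValueError("parents have incompatible architectures")


def recombine_one_point(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator | None = None,
    *,
    point: int | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Exchange all symbols beyond one shared crossover point."""
    _check_same_arch(parent_a, parent_b)
    fa, fb = _flatten(parent_a), _flatten(parent_b)
    if point is None:
        point = int(rng.integers(len(fa) + 1))
    ca = fa[:point] + fb[point:]
    cb = fb[:point] + fa[point:]
    arch = parent_a.architecture
    return _rebuild(ca, arch), _rebuild(cb, arch)


def recombine_two_point(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator | None = None,
    *,
    points: tuple[int, int] | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Exchange the symbols between two shared crossover points."""
    _check_same_arch(parent_a, parent_b)
    fa, fb = _flatten(parent_a), _flatten(parent_b)
    if points is None:
        i = int(rng.integers(len(fa) + 1))
        j = int(rng.integers(len(fa) + 1))
        points = (min(i, j), max(i, j))
    i, j = points
    ca = fa[:i] + fb[i:j] + fa[j:]
    cb = fb[:i] + fa[i:j] + fb[j:]
    arch = parent_a.architecture
    return _rebuild(ca, arch), _rebuild(cb, arch)


def recombine_gene(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator | None = None,
    *,
    index: int | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Swap a whole gene at the same location in both parents."""
    _check_same_arch(parent_a, parent_b)
    arch = parent_a.architecture
    if index is None:
        index = int(rng.integers(arch.gene_count))
    ga, gb = list(parent_a.genes), list(parent_b.genes)
    ga[index], gb[index] = gb[index], ga[index]
    return Chromosome(tuple(ga), arch), Chromosome(tuple(gb), parent_b.architecture)
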
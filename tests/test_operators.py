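"""Genetic operators: examples plus validity-preservation fuzzing."""

import numpy as np
import pytest

from gepcast.karva import Chromosome, GeneArchitecture, random_chromosome
from gepcast.operators import (
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

from conftest import BINARY_ONLY


def assert_valid(chrom):
    """Head/tail domain check (Chromosome validates on construction,
    re-run explicitly for clarity)."""
    arch = chrom.architecture
    for gene in chrom.genes:
        arch.validate_gene(gene)


# ---------------------------------------------------------------- selection

def test_select_replicate_replaces_worst_quarter_with_best():
    pop = ["w", "x", "y", "z"]
    fits = [4.0, 3.0, 2.0, 1.0]
    out = select_replicate(pop, fits)
    assert out == ["w", "x", "y", "w"]


def test_select_replicate_equal_fitness_keeps_order():
    pop = list("abcd")
    out = select_replicate(pop, [1.0] * 4)
    assert out == ["a", "b", "c", "a"]


def test_select_replicate_size_eight():
    pop = list(range(8))
    fits = [float(8 - i) for i in range(8)]
    out = select_replicate(pop, fits)
    assert out == [0, 1, 2, 3, 4, 5, 0, 1]


def test_select_replicate_never_decreases_max_fitness(rng):
    for _ in range(50):
        fits = list(rng.normal(size=10))
        out = select_replicate(list(range(10)), fits)
        assert max(fits[i] for i in out) == max(fits)


def test_select_replicate_empty_population_errors():
    with pytest.raises(ValueError):
        select_replicate([], [])


# ---------------------------------------------------------------- mutation

def test_mutation_rate_zero_is_identity(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    assert mutate(chrom, 0.0, rng) == chrom


def test_mutation_rate_one_with_singleton_sets_is_determined():
    arch = GeneArchitecture(head_len=2, gene_count=1, terminal_set=("t",),
                            function_set={"+": 2})
    chrom = random_chromosome(arch, np.random.default_rng(0))
    out = mutate(chrom, 1.0, np.random.default_rng(1))
    # head draws from {+, t}, tail forced to t
    assert all(s == "t" for s in out.genes[0][arch.head_len:])


def test_mutation_preserves_head_tail_domains(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    for _ in range(500):
        chrom = mutate(chrom, 0.3, rng)
        assert_valid(chrom)


# ---------------------------------------------------------------- transposition

def test_gene_transposition_moves_gene_to_front(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    g1, g2, g3, g4, g5 = chrom.genes
    out = transpose_gene(chrom, index=2)
    assert out.genes == (g3, g1, g2, g4, g5)


def test_is_transposition_noop_for_unit_head(rng):
    arch = GeneArchitecture(head_len=1, gene_count=2, terminal_set=("a", "b"),
                            function_set=dict(BINARY_ONLY))
    chrom = random_chromosome(arch, rng)
    assert transpose_is(chrom, rng) == chrom


def test_ris_requires_function_downstream(rng):
    # all-terminal heads: RIS can never find a function start, so no-op
    arch = GeneArchitecture(head_len=3, gene_count=1, terminal_set=("a",),
                            function_set=dict(BINARY_ONLY))
    chrom = Chromosome((("a", "a", "a", "a", "a", "a", "a"),), arch)
    for _ in range(20):
        assert transpose_ris(chrom, rng) == chrom


def test_transpositions_preserve_validity_and_tails(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    h = full_arch.head_len
    for _ in range(500):
        for op in (transpose_is, transpose_ris):
            before_tails = tuple(g[h:] for g in chrom.genes)
            out = op(chrom, rng)
            assert_valid(out)
            assert tuple(g[h:] for g in out.genes) == before_tails
        chrom = transpose_gene(chrom, rng)
        assert_valid(chrom)


# ---------------------------------------------------------------- recombination

def test_one_point_at_zero_swaps_parents(full_arch, rng):
    pa = random_chromosome(full_arch, rng)
    pb = random_chromosome(full_arch, rng)
    ca, cb = recombine_one_point(pa, pb, point=0)
    assert ca == pb and cb == pa


def test_identical_parents_breed_identical_children(full_arch, rng):
    p = random_chromosome(full_arch, rng)
    for op in (recombine_one_point, recombine_two_point, recombine_gene):
        ca, cb = op(p, p, rng)
        assert ca == p and cb == p


def test_two_point_with_equal_points_is_identity(full_arch, rng):
    pa = random_chromosome(full_arch, rng)
    pb = random_chromosome(full_arch, rng)
    ca, cb = recombine_two_point(pa, pb, points=(17, 17))
    assert ca == pa and cb == pb


def test_gene_recombination_swaps_one_gene(full_arch, rng):
    pa = random_chromosome(full_arch, rng)
    pb = random_chromosome(full_arch, rng)
    ca, cb = recombine_gene(pa, pb, index=3)
    assert ca.genes[3] == pb.genes[3] and cb.genes[3] == pa.genes[3]
    for i in (0, 1, 2, 4):
        assert ca.genes[i] == pa.genes[i] and cb.genes[i] == pb.genes[i]


# ---------------------------------------------------------------- inversion

def test_inversion_of_single_symbol_is_identity(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    assert invert(chrom, gene_index=0, span=(2, 3)) == chrom


def test_inversion_reverses_head_segment():
    arch = GeneArchitecture(head_len=3, gene_count=1, terminal_set=("a", "b"),
                            function_set=dict(BINARY_ONLY))
    chrom = Chromosome((("+", "-", "a", "b", "b", "a", "a"),), arch)
    out = invert(chrom, gene_index=0, span=(0, 3))
    assert out.genes[0] == ("a", "-", "+", "b", "b", "a", "a")


def test_inversion_never_touches_tail(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    h = full_arch.head_len
    for _ in range(500):
        out = invert(chrom, rng)
        assert_valid(out)
        assert tuple(g[h:] for g in out.genes) == tuple(g[h:] for g in chrom.genes)
        chrom = out


def test_inversion_rejects_span_into_tail(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    with pytest.raises(ValueError):
        invert(chrom, gene_index=0, span=(4, 8))


# ---------------------------------------------------------------- determinism

def test_operators_deterministic_under_seed(full_arch):
    chrom = random_chromosome(full_arch, np.random.default_rng(3))
    other = random_chromosome(full_arch, np.random.default_rng(4))
    for op in (transpose_is, transpose_ris, transpose_gene, invert):
        assert op(chrom, np.random.default_rng(9)) == op(
            chrom, np.random.default_rng(9)
        )
    for op in (recombine_one_point, recombine_two_point, recombine_gene):
        assert op(chrom, other, np.random.default_rng(9)) == op(
            chrom, other, np.random.default_rng(9)
        )
    assert mutate(chrom, 0.5, np.random.default_rng(9)) == mutate(
        chrom, 0.5, np.random.default_rng(9)
    )


def test_operator_rates_validated():
    with pytest.raises(ValueError):
        OperatorRates(mutation_p=1.5)
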
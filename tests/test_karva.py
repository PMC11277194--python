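"""K-expression representation: decoding, evaluation, serialization."""

import math

import numpy as np
import pytest

from gepcast.karva import (
    Chromosome,
    GeneArchitecture,
    TreeNode,
    decode_gene,
    encode_tree,
    evaluate_chromosome,
    evaluate_tree,
    parse_kexpression,
    random_chromosome,
    tail_length,
    to_kexpression,
)

from conftest import BINARY_ONLY


# ---------------------------------------------------------------- oracles

def decode_by_levels(gene, arch):
    """Independent decoder: slice the K-expression into tree levels by
    arity bookkeeping, then assemble recursively."""
    symbols = list(gene)
    levels = [[symbols[0]]]
    idx = 1
    while True:
        need = sum(arch.function_set.get(s, 0) for s in levels[-1])
        if need == 0:
            break
        levels.append(symbols[idx : idx + need])
        idx += need

    def build(level, pos):
        sym = levels[level][pos]
        arity = arch.function_set.get(sym, 0)
        if arity == 0:
            return TreeNode(sym)
        # children start after the children of earlier nodes on this level
        offset = sum(
            arch.function_set.get(s, 0) for s in levels[level][:pos]
        )
        kids = tuple(build(level + 1, offset + k) for k in range(arity))
        return TreeNode(sym, kids)

    return build(0, 0)


def eval_scalar(node, fm):
    """Brute-force recursive scalar evaluator with protected semantics."""
    if not node.children:
        return float(fm[node.symbol])
    args = [eval_scalar(c, fm) for c in node.children]
    try:
        if node.symbol == "+":
            return args[0] + args[1]
        if node.symbol == "-":
            return args[0] - args[1]
        if node.symbol == "*":
            return args[0] * args[1]
        if node.symbol == "/":
            return args[0] / args[1] if args[1] != 0 else math.nan
        if node.symbol == "sqrt":
            return math.sqrt(args[0]) if args[0] >= 0 else math.nan
        if node.symbol == "exp":
            return math.exp(args[0])
        if node.symbol == "ln":
            return math.log(args[0]) if args[0] > 0 else math.nan
        if node.symbol == "abs":
            return abs(args[0])
        if node.symbol == "sin":
            return math.sin(args[0])
        if node.symbol == "cos":
            return math.cos(args[0])
    except OverflowError:
        return math.inf
    raise KeyError(node.symbol)


# ---------------------------------------------------------------- tail rule

@pytest.mark.parametrize(
    "h,n,expected", [(6, 2, 7), (1, 2, 2), (3, 1, 1), (10, 1, 1), (4, 3, 9)]
)
def test_tail_length_formula(h, n, expected):
    assert tail_length(h, n) == expected


@pytest.mark.parametrize("h,n", [(0, 2), (3, 0), (-1, 2)])
def test_tail_length_rejects_nonpositive(h, n):
    with pytest.raises(ValueError):
        tail_length(h, n)


def test_tail_of_seven_completes_every_binary_head():
    """Exhaustive: every head of 6 symbols over binary functions and one
    terminal decodes to a complete tree using at most 7 tail terminals."""
    arch = GeneArchitecture(
        head_len=6, gene_count=1, terminal_set=("a",),
        function_set=dict(BINARY_ONLY),
    )
    pool = list(BINARY_ONLY) + ["a"]
    import itertools

    for head in itertools.product(pool, repeat=6):
        gene = tuple(head) + ("a",) * 7
        tree = decode_gene(gene, arch)
        for leaf_sym in encode_tree(tree):
            assert leaf_sym in pool


# ---------------------------------------------------------------- decoding

def test_decode_single_function():
    arch = GeneArchitecture(head_len=1, gene_count=1, terminal_set=("a", "b"),
                            function_set=dict(BINARY_ONLY))
    tree = decode_gene(("+", "a", "b"), arch)
    assert tree == TreeNode("+", (TreeNode("a"), TreeNode("b")))


def test_decode_terminal_root_ignores_rest(small_arch):
    gene = ("a", "+", "b", "c", "c", "a", "b")
    assert decode_gene(gene, small_arch) == TreeNode("a")


def test_decode_level_order_example(small_arch):
    # K-expression "* + c a b c c": level-order gives (a + b) * c
    gene = ("*", "+", "c", "a", "b", "c", "c")
    tree = decode_gene(gene, small_arch)
    expected = TreeNode(
        "*",
        (TreeNode("+", (TreeNode("a"), TreeNode("b"))), TreeNode("c")),
    )
    assert tree == expected
    assert tree == decode_by_levels(gene, small_arch)


def test_decode_matches_independent_decoder_fuzz(full_arch, rng):
    for _ in range(200):
        chrom = random_chromosome(full_arch, rng)
        for gene in chrom.genes:
            assert decode_gene(gene, full_arch) == decode_by_levels(gene, full_arch)


def test_roundtrip_level_order_prefix(full_arch, rng):
    """Re-encoding the decoded tree reproduces the used K-expression
    prefix."""
    for _ in range(200):
        chrom = random_chromosome(full_arch, rng)
        for gene in chrom.genes:
            prefix = encode_tree(decode_gene(gene, full_arch))
            assert tuple(prefix) == gene[: len(prefix)]


# ---------------------------------------------------------------- evaluation

def test_evaluate_simple_sum(small_arch):
    tree = decode_gene(("+", "a", "b", "a", "a", "a", "a"), small_arch)
    assert evaluate_tree(tree, {"a": 2.0, "b": 3.0}) == 5.0


def test_protected_division_yields_nonfinite(small_arch):
    tree = decode_gene(("/", "a", "b", "a", "a", "a", "a"), small_arch)
    assert not np.isfinite(evaluate_tree(tree, {"a": 1.0, "b": 0.0}))


def test_ln_abs_of_minus_one_is_zero():
    tree = TreeNode("ln", (TreeNode("abs", (TreeNode("x"),)),))
    assert evaluate_tree(tree, {"x": -1.0}) == 0.0


def test_protected_ln_sqrt_nonfinite():
    for sym, val in [("ln", -2.0), ("ln", 0.0), ("sqrt", -1.0)]:
        tree = TreeNode(sym, (TreeNode("x"),))
        assert not np.isfinite(evaluate_tree(tree, {"x": val}))


def test_chromosome_link_sums_gene_values():
    arch = GeneArchitecture(head_len=1, gene_count=5, terminal_set=("a",),
                            function_set=dict(BINARY_ONLY))
    genes = tuple((("a", "a", "a"),) * 5)
    chrom = Chromosome(genes, arch)
    assert evaluate_chromosome(chrom, {"a": 3.0}) == 15.0


def test_single_gene_chromosome_equals_tree(small_arch, rng):
    chrom = random_chromosome(small_arch, rng)
    fm = {"a": 1.3, "b": -0.4, "c": 2.2}
    tree_val = evaluate_tree(decode_gene(chrom.genes[0], small_arch), fm)
    chrom_val = evaluate_chromosome(chrom, fm)
    assert chrom_val == tree_val or (np.isnan(chrom_val) and np.isnan(tree_val))


def test_nonfinite_gene_poisons_chromosome():
    arch = GeneArchitecture(head_len=1, gene_count=2, terminal_set=("a", "b"),
                            function_set=dict(BINARY_ONLY))
    chrom = Chromosome((("a", "a", "a"), ("/", "a", "b")), arch)
    assert not np.isfinite(evaluate_chromosome(chrom, {"a": 1.0, "b": 0.0}))


def test_vectorized_matches_scalar_oracle(full_arch, rng):
    """Vectorized evaluation agrees with a brute-force recursive scalar
    evaluator case by case, to floating tolerance."""
    for _ in range(300):
        chrom = random_chromosome(full_arch, rng)
        fm_vec = {t: rng.uniform(-2, 2, size=4) for t in full_arch.terminal_set}
        vec = np.asarray(evaluate_chromosome(chrom, fm_vec), dtype=float)
        for j in range(4):
            fm = {t: float(v[j]) for t, v in fm_vec.items()}
            expected = sum(
                eval_scalar(decode_gene(g, full_arch), fm) for g in chrom.genes
            )
            if not np.isfinite(expected) or not np.isfinite(vec[j]):
                # protected semantics: both flag the case as non-finite
                assert not (np.isfinite(expected) and np.isfinite(vec[j]))
            else:
                assert vec[j] == pytest.approx(expected, abs=1e-12, rel=1e-9)


# ---------------------------------------------------------------- sampling

def test_random_chromosome_shape(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    assert len(chrom) == 5 * (6 + 7) == 65


def test_random_chromosome_seeded_determinism(full_arch):
    a = random_chromosome(full_arch, np.random.default_rng(7))
    b = random_chromosome(full_arch, np.random.default_rng(7))
    assert a == b


def test_random_chromosome_tail_is_terminal_only(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    for gene in chrom.genes:
        assert all(s in full_arch.terminal_set for s in gene[full_arch.head_len :])


def test_empty_symbol_sets_rejected():
    with pytest.raises(ValueError):
        GeneArchitecture(head_len=3, gene_count=1, terminal_set=())


# ---------------------------------------------------------------- text form

def test_kexpression_roundtrip(full_arch, rng):
    chrom = random_chromosome(full_arch, rng)
    text = to_kexpression(chrom)
    assert parse_kexpression(text, full_arch) == chrom
    assert text.count("|") == 4


def test_parse_rejects_invalid_tail(small_arch):
    with pytest.raises(ValueError):
        parse_kexpression("+ a b + a b c", small_arch)  # function in tail
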
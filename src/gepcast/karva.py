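"""K-expression genomes and their decoding into expression trees.

Gene expression programming (GEP) encodes a candidate formula as a
fixed-length linear string of symbols (a K-expression, or Karva string).
Each gene has a *head*, which may hold function or terminal symbols, and
a *tail* restricted to terminals.  With head length ``h`` and maximum
function arity ``n``, a tail of length ``t = h (n - 1) + 1`` guarantees
that every gene decodes to a complete expression tree regardless of the
symbols in the head, so random generation and genetic operators never
produce a syntactically invalid individual.

Decoding is breadth-first: symbols are read left to right and attached
as children of pending nodes in queue order; trailing symbols that are
never reached stay in the genome as dormant genetic material.

Numeric evaluation is *protected*: division by zero, logarithms of
non-positive values, square roots of negatives and overflow all yield a
non-finite value (NaN/inf) that propagates upward instead of raising.
The evolution engine maps non-finite results to a worst-fitness
sentinel, so no arbitrary substitution constant biases the search.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FUNCTION_SET",
    "GeneArchitecture",
    "Chromosome",
    "TreeNode",
    "tail_length",
    "decode_gene",
    "encode_tree",
    "evaluate_tree",
    "evaluate_gene",
    "evaluate_chromosome",
    "random_chromosome",
    "to_kexpression",
    "parse_kexpression",
]

#: Function symbols with their arities: the four binary arithmetic
#: operators plus six unary transforms.
DEFAULT_FUNCTION_SET: dict[str, int] = {
    "+": 2,
    "-": 2,
    "*": 2,
    "/": 2,
    "sqrt": 1,
    "exp": 1,
    "ln": 1,
    "abs": 1,
    "sin": 1,
    "cos": 1,
}


def tail_length(head_len: int, max_arity: int) -> int:
    """Tail length required for a head of ``head_len`` symbols.

    ``t = h (n - 1) + 1`` terminals are enough to complete any head into
    a full tree: the worst case is a head consisting entirely of
    max-arity functions.
    """
    if head_len < 1:
        raise ValueError(f"head_len must be >= 1, got {head_len}")
    if max_arity < 1:
        raise ValueError(f"max_arity must be >= 1, got {max_arity}")
    return head_len * (max_arity - 1) + 1


@dataclass
class GeneArchitecture:
    """Shape of every gene in a chromosome.

    Parameters
    ----------
    head_len
        Number of head positions per gene (functions or terminals).
    terminal_set
        Feature symbols usable as leaves.
    function_set
        Mapping from function symbol to arity.
    gene_count
        Genes per chromosome; per-gene values are folded with ``link_op``.
    link_op
        Associative binary function joining gene values (``"+"`` by
        default, matching an additive multigene model).
    """

    head_len: int
    terminal_set: tuple[str, ...]
    function_set: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTION_SET)
    )
    gene_count: int = 1
    link_op: str = "+"

    def __post_init__(self) -> None:
        self.terminal_set = tuple(self.terminal_set)
        if self.head_len < 1:
            raise ValueError("head_len must be >= 1")
        if self.gene_count < 1:
            raise ValueError("gene_count must be >= 1")
        if not self.terminal_set:
            raise ValueError("terminal_set must be nonempty")
        if not self.function_set:
            raise ValueError("function_set must be nonempty")
        overlap = set(self.function_set) & set(self.terminal_set)
        if overlap:
            raise ValueError(f"symbols used as both function and terminal: {overlap}")
        if self.link_op not in self.function_set or self.function_set[self.link_op] != 2:
            raise ValueError(f"link_op {self.link_op!r} must be a binary function")

    @property
    def max_arity(self) -> int:
        return max(self.function_set.values())

    @property
    def tail_len(self) -> int:
        return tail_length(self.head_len, self.max_arity)

    @property
    def gene_len(self) -> int:
        return self.head_len + self.tail_len

    @property
    def head_symbols(self) -> tuple[str, ...]:
        """Symbols admissible at head positions."""
        return tuple(self.function_set) + self.terminal_set

    def validate_gene(self, gene: Sequence[str]) -> None:
        if len(gene) != self.gene_len:
            raise ValueError(
                f"gene length {len(gene)} != head+tail {self.gene_len}"
            )
        allowed_head = set(self.function_set) | set(self.terminal_set)
        terminals = set(self.terminal_set)
        for i, sym in enumerate(gene):
            if i < self.head_len:
                if sym not in allowed_head:
                    raise ValueError(f"unknown head symbol {sym!r} at position {i}")
            elif sym not in terminals:
                raise ValueError(f"non-terminal {sym!r} in tail at position {i}")


@dataclass
class Chromosome:
    """A sequence of genes sharing one :class:`GeneArchitecture`."""

    genes: tuple[tuple[str, ...], ...]
    architecture: GeneArchitecture

    def __post_init__(self) -> None:
        self.genes = tuple(tuple(g) for g in self.genes)
        arch = self.architecture
        if len(self.genes) != arch.gene_count:
            raise ValueError(
                f"expected {arch.gene_count} genes, got {len(self.genes)}"
            )
        for g in self.genes:
            arch.validate_gene(g)

    def __len__(self) -> int:
        return self.architecture.gene_count * self.architecture.gene_len

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromosome):
            return NotImplemented
        return self.genes == other.genes


@dataclass(frozen=True)
class TreeNode:
    """Expression-tree node: a terminal leaf or a function with children."""

    symbol: str
    children: tuple["TreeNode", ...] = ()


def decode_gene(gene: Sequence[str], architecture: GeneArchitecture) -> TreeNode:
    """Decode a K-expression gene into its expression tree.

    Level-order filling: the first symbol is the root; subsequent
    symbols are attached as children of pending nodes in queue order
    until every function node has its full complement of children.
    Unused trailing symbols are ignored.
    """
    functions = architecture.function_set
    symbols = list(gene)
    root_sym = symbols[0]
    # mutable scaffold: [symbol, child_list]
    root = [root_sym, []]
    pending: deque = deque()
    if root_sym in functions:
        pending.append((root, functions[root_sym]))
    idx = 1
    while pending:
        node, need = pending.popleft()
        for _ in range(need):
            if idx >= len(symbols):
                raise ValueError("gene exhausted before tree completed")
            sym = symbols[idx]
            idx += 1
            child = [sym, []]
            node[1].append(child)
            if sym in functions:
                pending.append((child, functions[sym]))

    def freeze(n: list) -> TreeNode:
        return TreeNode(n[0], tuple(freeze(c) for c in n[1]))

    return freeze(root)


def encode_tree(tree: TreeNode) -> list[str]:
    """Level-order linearization of a tree (inverse of :func:`decode_gene`
    on the used prefix of a gene)."""
    out: list[str] = []
    queue: deque[TreeNode] = deque([tree])
    while queue:
        node = queue.popleft()
        out.append(node.symbol)
        queue.extend(node.children)
    return out


def _apply(symbol: str, args: list[np.ndarray]) -> np.ndarray:
    with np.errstate(all="ignore"):
        if symbol == "+":
            return args[0] + args[1]
        if symbol == "-":
            return args[0] - args[1]
        if symbol == "*":
            return args[0] * args[1]
        if symbol == "/":
            return args[0] / args[1]
        if symbol == "sqrt":
            return np.sqrt(args[0])
        if symbol == "exp":
            return np.exp(args[0])
        if symbol == "ln":
            return np.log(args[0])
        if symbol == "abs":
            return np.abs(args[0])
        if symbol == "sin":
            return np.sin(args[0])
        if symbol == "cos":
            return np.cos(args[0])
    raise KeyError(f"unknown function symbol {symbol!r}")


def evaluate_tree(
    tree: TreeNode, feature_map: Mapping[str, float | np.ndarray]
) -> np.ndarray | float:
    """Evaluate a tree on scalar or vector terminal values.

    Vector inputs evaluate all fitness cases at once.  Protected
    semantics: invalid operations yield NaN/inf entries rather than
    raising, and non-finite values propagate upward.
    """
    scalar = not any(np.ndim(v) > 0 for v in feature_map.values())

    def rec(node: TreeNode) -> np.ndarray:
        if not node.children:
            return np.asarray(feature_map[node.symbol], dtype=float)
        return _apply(node.symbol, [rec(c) for c in node.children])

    result = rec(tree)
    return float(result) if scalar and np.ndim(result) == 0 else result


def evaluate_gene(
    gene: Sequence[str],
    architecture: GeneArchitecture,
    feature_map: Mapping[str, float | np.ndarray],
) -> np.ndarray | float:
    return evaluate_tree(decode_gene(gene, architecture), feature_map)


def evaluate_chromosome(
    chromosome: Chromosome, feature_map: Mapping[str, float | np.ndarray]
) -> np.ndarray | float:
    """Fold per-gene tree values with the architecture's link function.

    A non-finite value in any gene makes the chromosome value
    non-finite for that case.
    """
    arch = chromosome.architecture
    values = [evaluate_gene(g, arch, feature_map) for g in chromosome.genes]
    acc = np.asarray(values[0], dtype=float)
    for v in values[1:]:
        acc = _apply(arch.link_op, [acc, np.asarray(v, dtype=float)])
    scalar = not any(np.ndim(v) > 0 for v in feature_map.values())
    return float(acc) if scalar and np.ndim(acc) == 0 else acc


def random_chromosome(
    architecture: GeneArchitecture, rng: np.random.Generator
) -> Chromosome:
    """Sample a valid chromosome: head positions uniform over functions
    plus terminals, tail positions uniform over terminals."""
    head_pool = architecture.head_symbols
    term_pool = architecture.terminal_set
    genes = []
    for _ in range(architecture.gene_count):
        head = [head_pool[rng.integers(len(head_pool))] for _ in range(architecture.head_len)]
        tail = [term_pool[rng.integers(len(term_pool))] for _ in range(architecture.tail_len)]
        genes.append(tuple(head + tail))
    return Chromosome(tuple(genes), architecture)


def to_kexpression(chromosome: Chromosome) -> str:
    """Serialize to plain text: symbols space-separated, genes joined
    by ``"|"``."""
    return "|".join(" ".join(g) for g in chromosome.genes)


def parse_kexpression(text: str, architecture: GeneArchitecture) -> Chromosome:
    """Inverse of :func:`to_kexpression`; validates against the
    architecture."""
    genes = tuple(tuple(part.split()) for part in text.split("|"))
    return Chromosome(genes, architecture)
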
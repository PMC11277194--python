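import numpy as np
import pytest

from gepcast.karva import GeneArchitecture

BINARY_ONLY = {"+": 2, "-": 2, "*": 2, "/": 2}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_arch():
    """Single gene, binary functions only, three terminals."""
    return GeneArchitecture(
        head_len=3, gene_count=1, terminal_set=("a", "b", "c"),
        function_set=dict(BINARY_ONLY),
    )


@pytest.fixture
def full_arch():
    """The standard genome: head 6, five genes, ten functions, x1..x14."""
    return GeneArchitecture(
        head_len=6, gene_count=5,
        terminal_set=tuple(f"x{i + 1}" for i in range(14)),
    )
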
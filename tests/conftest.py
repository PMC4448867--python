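import pytest

from targetrank.graph import build_graph
from targetrank.mitab import AccessionPair


def pairs(*edges: tuple[str, str]) -> list[AccessionPair]:
    return [AccessionPair(a, b) for a, b in edges]


@pytest.fixture
def path_graph():
    """Two vertices joined by one edge (a--b)."""
    return build_graph(pairs(("P00001", "P00002")))


@pytest.fixture
def k4_graph():
    accs = ["P00001", "P00002", "P00003", "P00004"]
    return build_graph(pairs(*[(a, b) for i, a in enumerate(accs) for b in accs[i + 1 :]]))


@pytest.fixture
def triangle_loop_graph():
    """a-b, b-c, a-c plus a self-loop at c: 7 directed edges."""
    return build_graph(pairs(("A", "B"), ("B", "C"), ("A", "C"), ("C", "C")))
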
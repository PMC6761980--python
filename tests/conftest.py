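import random

import pytest

from graphaln.graph import SequenceGraph


def random_graph(rng: random.Random, n_max: int = 25, cyclic: bool = True,
                 density: float = 3.0) -> SequenceGraph:
    """Random node-labeled graph; acyclic if ``cyclic`` is False (edges only
    forward in id order)."""
    n = rng.randint(1, n_max)
    g = SequenceGraph()
    for _ in range(n):
        g.add_node(rng.choice("ACGT"))
    for _ in range(rng.randint(0, int(density * n))):
        u, v = rng.randrange(n), rng.randrange(n)
        if not cyclic and u >= v:
            continue
        g.add_edge(u, v)
    return g


def random_graph_with_loops(rng: random.Random, n_max: int = 20) -> SequenceGraph:
    """Cyclic graph guaranteed to contain a self-loop and a 2-cycle when
    large enough."""
    g = random_graph(rng, n_max=n_max, cyclic=True)
    n = g.node_count
    g.add_edge(rng.randrange(n), rng.randrange(n))
    v = rng.randrange(n)
    g.add_edge(v, v)  # self-loop
    if n >= 2:
        a, b = rng.sample(range(n), 2)
        g.add_edge(a, b)
        g.add_edge(b, a)  # 2-cycle
    return g


@pytest.fixture
def rng():
    return random.Random(0xC0FFEE)
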
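import itertools
import random

import pytest

from rpatopo.network import Network


@pytest.fixture
def fig2a_net():
    return Network.from_edges(
        [("X", "O", "activating"), ("O", "X", "inhibiting")], "X", "X")


@pytest.fixture
def fig2b_net():
    return Network.from_edges(
        [("D", "B", "activating"), ("B", "C", "activating"),
         ("D", "C", "inhibiting")], "D", "C")


def random_network(rng: random.Random, n_max: int = 6,
                   p: float = 0.45) -> Network | None:
    """A random connected-input network, or None when output unreachable."""
    n = rng.randint(2, n_max)
    nodes = [f"n{i}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.permutations(nodes, 2)
             if rng.random() < p]
    output = nodes[rng.randrange(n)]
    try:
        return Network.from_edges(edges, "n0", output, nodes=nodes)
    except Exception:
        return None


def complete_digraph(n: int) -> Network:
    nodes = [f"n{i}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.permutations(nodes, 2)]
    return Network.from_edges(edges, nodes[0], nodes[1])
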
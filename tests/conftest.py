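import random

import pytest

from orbitcount.graph_store import EdgeModification, Graph, Op
from orbitcount.taxonomy import build_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return build_catalogue()


@pytest.fixture
def triangle():
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def k5():
    return Graph.from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


def random_er_graph(rng: random.Random, n: int, p: float) -> Graph:
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return Graph.from_edges(n, edges)


def random_modification(rng: random.Random, g: Graph):
    """A valid ADD or REMOVE for g, or None if neither exists."""
    present = sorted(g.edges())
    absent = [
        (i, j)
        for i in range(g.n)
        for j in range(i + 1, g.n)
        if not g.has_edge(i, j)
    ]
    choices = []
    if absent:
        choices.append(Op.ADD)
    if present:
        choices.append(Op.REMOVE)
    if not choices:
        return None
    op = rng.choice(choices)
    u, v = rng.choice(absent if op is Op.ADD else present)
    return EdgeModification(op, u, v)
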
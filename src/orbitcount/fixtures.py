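"""Programmatic fixtures: named toy graphs and the planted regulatory-network
benchmark used to exercise the redundancy optimiser.

``planted_grn`` emulates the structure the optimiser targets: a sparse
scale-free "true" network whose edges carry noisy high scores, contaminated
by dense clique edges concentrated around hubs (false positives that inflate
graphlet redundancy), plus low-scoring random padding.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .exceptions import DomainError
from .graph_store import Graph
from .redundancy_optimiser import RankedEdge, RankedEdgeList

TOY_GRAPHS: Dict[str, Tuple[int, List[Tuple[int, int]]]] = {
    "edge": (2, [(0, 1)]),
    "path": (3, [(0, 1), (1, 2)]),
    "triangle": (3, [(0, 1), (1, 2), (0, 2)]),
    "C4": (4, [(0, 1), (1, 2), (2, 3), (0, 3)]),
    "C5": (5, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]),
    "K4": (4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
    "K5": (5, [(i, j) for i in range(5) for j in range(i + 1, 5)]),
    "star": (11, [(0, i) for i in range(1, 11)]),
}


def toy_graph(name: str) -> Tuple[Graph, List[str]]:
    if name not in TOY_GRAPHS:
        raise DomainError(f"unknown toy graph {name!r}; options: {sorted(TOY_GRAPHS)}")
    n, edges = TOY_GRAPHS[name]
    return Graph.from_edges(n, edges), [f"n{i}" for i in range(n)]


def _preferential_tree(n: int, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Scale-free tree: each new node attaches to a degree-weighted target."""
    edges = [(0, 1)]
    pool = [0, 1]  # degree-proportional sampling pool
    for new in range(2, n):
        t = pool[int(rng.integers(len(pool)))]
        edges.append((t, new))
        pool.extend((t, new))
    return edges


def planted_grn(n: int = 100, seed: int = 0, n_cliques: int = 3, clique_size: int = 6,
                n_noise: int = 150):
    """Build (ranked list, gold standard, labels).

    * true network: preferential-attachment tree on ``n`` genes, edge scores
      drawn from U(0.55, 1.0);
    * false positives: edges completing cliques around the tree's hubs,
      scores U(0.5, 0.95) — interleaved with (and often above) true edges;
    * padding: random absent pairs scored U(0.0, 0.5).
    """
    if n < 20:
        raise DomainError("planted_grn needs at least 20 genes")
    rng = np.random.default_rng(seed)
    labels = [f"g{i:03d}" for i in range(n)]
    truth = _preferential_tree(n, rng)
    truth_set = {tuple(sorted(e)) for e in truth}

    degree = np.zeros(n, dtype=int)
    for u, v in truth:
        degree[u] += 1
        degree[v] += 1
    hubs = list(np.argsort(degree)[::-1][:n_cliques])

    adj = {i: set() for i in range(n)}
    for u, v in truth:
        adj[u].add(v)
        adj[v].add(u)

    false_edges: Set[Tuple[int, int]] = set()
    for hub in hubs:
        members = [int(hub)]
        neigh = sorted(adj[int(hub)])
        rng.shuffle(neigh)
        members.extend(neigh[: clique_size - 1])
        while len(members) < clique_size:
            cand = int(rng.integers(n))
            if cand not in members:
                members.append(cand)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair = (a, b) if a < b else (b, a)
                if pair not in truth_set:
                    false_edges.add(pair)

    used = truth_set | false_edges
    noise: Set[Tuple[int, int]] = set()
    while len(noise) < n_noise:
        a, b = int(rng.integers(n)), int(rng.integers(n))
        if a == b:
            continue
        pair = (a, b) if a < b else (b, a)
        if pair not in used and pair not in noise:
            noise.add(pair)

    records = []
    for u, v in truth_set:
        records.append(RankedEdge(labels[u], labels[v], float(rng.uniform(0.55, 1.0))))
    for u, v in false_edges:
        records.append(RankedEdge(labels[u], labels[v], float(rng.uniform(0.5, 0.95))))
    for u, v in noise:
        records.append(RankedEdge(labels[u], labels[v], float(rng.uniform(0.0, 0.5))))
    records.sort(key=lambda r: -r.score)
    ranked = RankedEdgeList(records)
    gold = {(labels[u], labels[v]) for u, v in truth_set}
    return ranked, gold, labels
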
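"""Non-incremental orbit counting over all connected induced 2-5 node subgraphs.

``count_all`` enumerates every connected induced subgraph exactly once using
expansion with exclusion sets (each subgraph is generated from its minimum
node, and newly reachable candidates are restricted to nodes not already
adjacent to the current set), classifies it through the taxonomy lookup
table, and accumulates per-node orbit counts plus per-class totals.

``count_all_brute`` is the deliberately independent oracle: it tests all node
subsets directly and classifies induced subgraphs by permutation search
against the catalogue representatives, sharing no code with the lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Optional, Sequence, TextIO

import numpy as np

from . import taxonomy
from .exceptions import DomainError
from .graph_store import Graph
from .taxonomy import N_GRAPHLETS, N_ORBITS, PAIRS

MAX_SIZE = 5
BRUTE_NODE_GUARD = 40


@dataclass
class CountMatrix:
    """n x 73 matrix; entry [i, j] counts node i's appearances at orbit j."""

    counts: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "CountMatrix":
        return cls(np.zeros((n, N_ORBITS), dtype=np.int64))

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and np.array_equal(
            self.counts, other.counts
        )


@dataclass
class GraphletTotals:
    """Occurrences per graphlet class, length 30."""

    values: np.ndarray

    @classmethod
    def zeros(cls) -> "GraphletTotals":
        return cls(np.zeros(N_GRAPHLETS, dtype=np.int64))

    def copy(self) -> "GraphletTotals":
        return GraphletTotals(self.values.copy())

    @property
    def n_subgraphs(self) -> int:
        """Total connected induced 2-5 node subgraphs (one count each)."""
        return int(self.values.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, GraphletTotals) and np.array_equal(
            self.values, other.values
        )


def connected_subsets(graph: Graph, max_size: int = MAX_SIZE):
    """Yield every connected node set of size 2..max_size exactly once.

    Expansion with exclusion: sets are rooted at their minimum node; the
    extension list only ever receives nodes larger than the root that are
    not yet adjacent to the current set, and a candidate consumed at one
    branch is excluded from all its siblings.
    """
    for root in range(graph.n):
        ext = [u for u in graph.neighbors(root) if u > root]
        if ext:
            yield from _extend(graph, (root,), ext, set(graph.neighbors(root)) | {root}, root, max_size)


def _extend(graph, sub, ext, closed, root, max_size):
    while ext:
        w = ext.pop()
        new_sub = sub + (w,)
        yield new_sub
        if len(new_sub) < max_size:
            fresh = [u for u in graph.neighbors(w) if u > root and u not in closed]
            yield from _extend(
                graph, new_sub, ext + fresh, closed | set(graph.neighbors(w)), root, max_size
            )


def _accumulate(graph: Graph, node_sets, counts: np.ndarray, totals: np.ndarray,
                lookup, sign: int = 1):
    adj = graph._adj
    for sub in node_sets:
        st = sorted(sub)
        s = len(st)
        mask = 0
        for rank, (i, j) in enumerate(PAIRS[s]):
            if st[j] in adj[st[i]]:
                mask |= 1 << rank
        gid, orbits = lookup[s][mask]
        totals[gid] += sign
        for node, orb in zip(st, orbits):
            counts[node, orb] += sign


def count_all(graph: Graph):
    """Count all orbits; returns ``(CountMatrix, GraphletTotals)``."""
    cat = taxonomy.build_catalogue()
    cm = CountMatrix.zeros(graph.n)
    tot = GraphletTotals.zeros()
    _accumulate(graph, connected_subsets(graph), cm.counts, tot.values, cat.lookup)
    return cm, tot


# -- independent brute-force oracle -----------------------------------


def _brute_classify(edge_set: frozenset, size: int, cat):
    """Classify by permutation search against catalogue representatives."""
    for g in cat.graphlets:
        if g.size != size or len(g.edges) != len(edge_set):
            continue
        for perm in permutations(range(size)):
            mapped = frozenset(
                (perm[i], perm[j]) if perm[i] < perm[j] else (perm[j], perm[i])
                for i, j in edge_set
            )
            if mapped == g.edges:
                # position i sits at representative position perm[i]
                return g.id, tuple(g.orbit_of_position[perm[i]] for i in range(size))
    return None  # disconnected (or impossible)


def _subset_connected(nodes, adj) -> bool:
    nodes = list(nodes)
    seen = {nodes[0]}
    stack = [nodes[0]]
    members = set(nodes)
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in members and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(nodes)


def count_all_brute(graph: Graph):
    """Subset-by-subset oracle counter; guarded to small graphs."""
    if graph.n > BRUTE_NODE_GUARD:
        raise DomainError(
            f"brute-force counter is limited to {BRUTE_NODE_GUARD} nodes, got {graph.n}"
        )
    cat = taxonomy.build_catalogue()
    cm = CountMatrix.zeros(graph.n)
    tot = GraphletTotals.zeros()
    adj = graph._adj
    cache: dict = {}
    for size in range(2, MAX_SIZE + 1):
        for subset in combinations(range(graph.n), size):
            edge_set = frozenset(
                (u, v) for u, v in combinations(subset, 2) if v in adj[u]
            )
            if not edge_set or not _subset_connected(subset, adj):
                continue
            local = frozenset(
                (subset.index(u), subset.index(v)) for u, v in edge_set
            )
            key = (size, local)
            if key not in cache:
                cache[key] = _brute_classify(local, size, cat)
            entry = cache[key]
            if entry is None:
                continue
            gid, orbits = entry
            tot.values[gid] += 1
            for node, orb in zip(subset, orbits):
                cm.counts[node, orb] += 1
    return cm, tot


# -- TSV I/O ----------------------------------------------------------


def write_count_matrix(handle: TextIO, cm: CountMatrix, labels: Optional[Sequence] = None):
    if labels is None:
        labels = [str(i) for i in range(cm.n)]
    handle.write("node\t" + "\t".join(f"O{j}" for j in range(N_ORBITS)) + "\n")
    for i in range(cm.n):
        handle.write(labels[i] + "\t" + "\t".join(map(str, cm.counts[i])) + "\n")


def read_count_matrix(handle: TextIO):
    header = handle.readline()
    labels, rows = [], []
    for line in handle:
        toks = line.rstrip("\n").split("\t")
        labels.append(toks[0])
        rows.append([int(t) for t in toks[1:]])
    arr = np.array(rows, dtype=np.int64).reshape(len(rows), N_ORBITS)
    return CountMatrix(arr), labels


def write_totals(handle: TextIO, tot: GraphletTotals):
    handle.write("graphlet\tcount\n")
    for g in range(N_GRAPHLETS):
        handle.write(f"G{g}\t{tot.values[g]}\n")


def read_totals(handle: TextIO) -> GraphletTotals:
    handle.readline()
    tot = GraphletTotals.zeros()
    for line in handle:
        name, value = line.split()
        tot.values[int(name.lstrip("G"))] = int(value)
    return tot
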
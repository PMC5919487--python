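"""Undirected simple-graph container with bit-packed adjacency and edge-list I/O.

The adjacency relation is stored twice: as a full n x n bit matrix packed 32
booleans per 4-byte word (the memory-frugal representation that fits 92681
nodes into 2^30 bytes), and as per-node neighbour sets, which the subgraph
enumerators iterate over.  Above a configurable node-count cutoff the bit
matrix is dropped and only neighbour sets are kept.

Node ids are dense 0-based integers; external string labels are mapped via a
symbol table at I/O time.  The edge-list format is two whitespace-separated
label columns, ``#``-prefixed comment lines, and single-token lines declaring
isolated nodes (so graphs with degree-0 nodes round-trip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np

from .exceptions import DomainError, ParseError, PreconditionError

#: adjacency booleans packed per machine word
WORD_BYTES = 4
BITS_PER_WORD = WORD_BYTES * 8

#: default node-count cutoff above which the bit matrix is not materialised
DEFAULT_PACKED_CUTOFF = 20_000


class Op(Enum):
    ADD = "+"
    REMOVE = "-"


@dataclass(frozen=True)
class EdgeModification:
    op: Op
    u: int
    v: int

    def __post_init__(self):
        if self.u == self.v:
            raise DomainError(f"self-loop modification on node {self.u}")

    @property
    def edge(self):
        return (self.u, self.v) if self.u < self.v else (self.v, self.u)

    def inverse(self) -> "EdgeModification":
        other = Op.REMOVE if self.op is Op.ADD else Op.ADD
        return EdgeModification(other, self.u, self.v)


class Graph:
    """Undirected simple graph over nodes ``0 .. n-1``."""

    def __init__(self, n: int, packed_cutoff: int = DEFAULT_PACKED_CUTOFF):
        if n < 0:
            raise DomainError("node count must be non-negative")
        self.n = n
        self._adj = [set() for _ in range(n)]
        self._n_edges = 0
        self._packed: Optional[np.ndarray]
        if n <= packed_cutoff:
            words = (n + BITS_PER_WORD - 1) // BITS_PER_WORD if n else 0
            self._packed = np.zeros((n, words), dtype=np.uint32)
        else:
            self._packed = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, n: int, edges: Iterable, **kw) -> "Graph":
        g = cls(n, **kw)
        for u, v in edges:
            g.add_edge(u, v)
        return g

    def copy(self) -> "Graph":
        g = Graph.__new__(Graph)
        g.n = self.n
        g._adj = [set(s) for s in self._adj]
        g._n_edges = self._n_edges
        g._packed = None if self._packed is None else self._packed.copy()
        return g

    # -- queries ------------------------------------------------------

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._adj[u]

    def _packed_bit(self, u: int, v: int) -> bool:
        w, b = divmod(v, BITS_PER_WORD)
        return bool(self._packed[u, w] >> b & 1)

    def neighbors(self, u: int) -> set:
        return self._adj[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self._adj], dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def edges(self) -> Iterator:
        for u in range(self.n):
            for v in self._adj[u]:
                if u < v:
                    yield (u, v)

    # -- mutation -----------------------------------------------------

    def _check(self, u: int, v: int):
        if u == v:
            raise DomainError(f"self-loop on node {u}")
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise DomainError(f"edge ({u}, {v}) outside node range [0, {self.n})")

    def add_edge(self, u: int, v: int):
        self._check(u, v)
        if v in self._adj[u]:
            raise PreconditionError(f"ADD of existing edge ({u}, {v})")
        self._adj[u].add(v)
        self._adj[v].add(u)
        self._n_edges += 1
        if self._packed is not None:
            wu, bu = divmod(v, BITS_PER_WORD)
            wv, bv = divmod(u, BITS_PER_WORD)
            self._packed[u, wu] |= np.uint32(1 << bu)
            self._packed[v, wv] |= np.uint32(1 << bv)

    def remove_edge(self, u: int, v: int):
        self._check(u, v)
        if v not in self._adj[u]:
            raise PreconditionError(f"REMOVE of absent edge ({u}, {v})")
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._n_edges -= 1
        if self._packed is not None:
            wu, bu = divmod(v, BITS_PER_WORD)
            wv, bv = divmod(u, BITS_PER_WORD)
            self._packed[u, wu] &= np.uint32(~(1 << bu) & 0xFFFFFFFF)
            self._packed[v, wv] &= np.uint32(~(1 << bv) & 0xFFFFFFFF)


def apply(graph: Graph, mod: EdgeModification) -> Graph:
    """Apply one edge modification in place; returns the same graph."""
    if mod.op is Op.ADD:
        graph.add_edge(mod.u, mod.v)
    else:
        graph.remove_edge(mod.u, mod.v)
    return graph


def packed_capacity(memory_budget: int) -> int:
    """Largest n whose full n^2-bit packed adjacency matrix fits the budget.

    A gigabyte is read as 2^30 bytes; ``packed_capacity(2**30) == 92681``.
    """
    if memory_budget <= 0:
        raise DomainError("memory budget must be positive")
    return math.isqrt(memory_budget * 8)


def h_index(graph: Graph) -> int:
    """Largest h such that at least h nodes have degree >= h."""
    degs = sorted((len(s) for s in graph._adj), reverse=True)
    h = 0
    for i, d in enumerate(degs, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


# -- edge-list I/O ----------------------------------------------------


def read_edge_list(handle: TextIO, packed_cutoff: int = DEFAULT_PACKED_CUTOFF):
    """Parse an edge list; returns ``(Graph, labels)``.

    Lines: ``# comment``, ``label`` (isolated-node declaration) or
    ``label label`` (edge).  Self-loops and duplicate edges are parse errors.
    """
    labels: list = []
    index: dict = {}
    edges = []

    def node(tok):
        if tok not in index:
            index[tok] = len(labels)
            labels.append(tok)
        return index[tok]

    seen = set()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) == 1:
            node(toks[0])
        elif len(toks) == 2:
            u, v = node(toks[0]), node(toks[1])
            if u == v:
                raise ParseError(lineno, f"self-loop on node {toks[0]!r}")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise ParseError(lineno, f"duplicate edge {toks[0]!r} {toks[1]!r}")
            seen.add(key)
            edges.append(key)
        else:
            raise ParseError(lineno, f"expected 1 or 2 columns, got {len(toks)}")
    g = Graph.from_edges(len(labels), edges, packed_cutoff=packed_cutoff)
    return g, labels


def write_edge_list(handle: TextIO, graph: Graph, labels: Optional[Sequence] = None):
    if labels is None:
        labels = [str(i) for i in range(graph.n)]
    for u in range(graph.n):
        if graph.degree(u) == 0:
            handle.write(f"{labels[u]}\n")
    for u, v in sorted(graph.edges()):
        handle.write(f"{labels[u]}\t{labels[v]}\n")


# -- modification-stream I/O ------------------------------------------

_OPS = {"+": Op.ADD, "-": Op.REMOVE, "−": Op.REMOVE}


def read_stream(handle: TextIO, labels: Sequence) -> list:
    """Parse a modification stream TSV: (op in {+,-}, label, label)."""
    index = {lab: i for i, lab in enumerate(labels)}
    mods = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 3:
            raise ParseError(lineno, f"expected 3 columns, got {len(toks)}")
        op, a, b = toks
        if op not in _OPS:
            raise ParseError(lineno, f"unknown operation {op!r}")
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ParseError(lineno, f"unknown node label {missing!r}")
        try:
            mods.append(EdgeModification(_OPS[op], index[a], index[b]))
        except DomainError as exc:
            raise ParseError(lineno, str(exc)) from exc
    return mods


def write_stream(handle: TextIO, mods: Iterable, labels: Optional[Sequence] = None):
    handle.write("# op\tu\tv\n")
    for m in mods:
        u = labels[m.u] if labels is not None else str(m.u)
        v = labels[m.v] if labels is not None else str(m.v)
        handle.write(f"{m.op.value}\t{u}\t{v}\n")
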
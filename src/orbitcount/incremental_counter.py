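"""Signed orbit-count deltas for single-edge modifications.

Instead of recounting the whole network after an edge change, only the node
sets whose induced subgraph is affected are enumerated: every connected set
of 2-5 nodes containing *both* endpoints of the modified edge.  Enumeration
always runs in the edge-present graph (the post-add state for additions, the
pre-remove state for removals): a set connected in only one of the two
states is necessarily connected in the edge-present one, so this single
enumeration covers all changed sets.  Each set is classified twice via two
masks differing in exactly the modified edge's bit; the disconnected side
contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, TextIO, Tuple

import numpy as np

from . import taxonomy
from .exceptions import PreconditionError, StreamError
from .graph_store import EdgeModification, Graph, Op, apply
from .static_counter import CountMatrix, GraphletTotals, count_all
from .taxonomy import N_GRAPHLETS, PAIR_RANK, PAIRS

MAX_SIZE = 5


@dataclass
class DeltaMatrix:
    """Sparse signed orbit-count differences plus graphlet-total deltas."""

    entries: Dict[Tuple[int, int], int] = field(default_factory=dict)
    totals: np.ndarray = field(default_factory=lambda: np.zeros(N_GRAPHLETS, dtype=np.int64))
    visited_sets: int = 0  # instrumentation: node sets enumerated

    def _bump(self, node: int, orbit: int, sign: int):
        key = (node, orbit)
        val = self.entries.get(key, 0) + sign
        if val:
            self.entries[key] = val
        else:
            self.entries.pop(key, None)

    def support_nodes(self) -> set:
        return {node for node, _ in self.entries}

    def add_to(self, cm: CountMatrix, tot: GraphletTotals):
        for (node, orbit), val in self.entries.items():
            cm.counts[node, orbit] += val
        tot.values += self.totals

    def __add__(self, other: "DeltaMatrix") -> "DeltaMatrix":
        out = DeltaMatrix(dict(self.entries), self.totals + other.totals)
        for (node, orbit), val in other.entries.items():
            out._bump(node, orbit, val)
        return out

    def is_zero(self) -> bool:
        return not self.entries and not self.totals.any()


def changed_sets(graph_with_edge: Graph, u: int, v: int) -> Iterator[tuple]:
    """Yield each connected 2-5 node set containing both u and v exactly once.

    Same exclusion-set expansion as the static enumerator, but seeded with
    the edge's endpoints instead of a single root; all yielded nodes lie
    within distance 3 of u or v because the sets are connected and small.
    """
    if not graph_with_edge.has_edge(u, v):
        raise PreconditionError(f"edge ({u}, {v}) not present in graph")
    yield (u, v)
    closed = {u, v} | graph_with_edge.neighbors(u) | graph_with_edge.neighbors(v)
    ext = [w for w in closed if w != u and w != v]
    yield from _extend(graph_with_edge, (u, v), ext, closed)


def _extend(graph, sub, ext, closed):
    while ext:
        w = ext.pop()
        new_sub = sub + (w,)
        yield new_sub
        if len(new_sub) < MAX_SIZE:
            fresh = [x for x in graph.neighbors(w) if x not in closed]
            yield from _extend(graph, new_sub, ext + fresh, closed | set(graph.neighbors(w)))


def delta(graph: Graph, mod: EdgeModification) -> DeltaMatrix:
    """Delta such that counts(post-state) = counts(pre-state) + delta.

    ``graph`` is the pre-modification state; it is returned unmodified
    (an ADD is applied and reverted internally).
    """
    u, v = mod.u, mod.v
    if mod.op is Op.ADD:
        if graph.has_edge(u, v):
            raise PreconditionError(f"ADD of existing edge ({u}, {v})")
        graph.add_edge(u, v)
        try:
            d = _edge_delta(graph, u, v, sign=+1)
        finally:
            graph.remove_edge(u, v)
    else:
        if not graph.has_edge(u, v):
            raise PreconditionError(f"REMOVE of absent edge ({u}, {v})")
        d = _edge_delta(graph, u, v, sign=-1)
    return d


def _edge_delta(gw: Graph, u: int, v: int, sign: int) -> DeltaMatrix:
    """Core loop: gw has the edge; sign +1 counts with-edge as 'after'."""
    cat = taxonomy.build_catalogue()
    lookup = cat.lookup
    adj = gw._adj
    d = DeltaMatrix()
    totals = d.totals
    entries: Dict[Tuple[int, int], int] = d.entries

    for sub in changed_sets(gw, u, v):
        d.visited_sets += 1
        st = sorted(sub)
        s = len(st)
        mask = 0
        for rank, (i, j) in enumerate(PAIRS[s]):
            if st[j] in adj[st[i]]:
                mask |= 1 << rank
        iu, iv = st.index(u), st.index(v)
        if iu > iv:
            iu, iv = iv, iu
        bit = 1 << PAIR_RANK[s][(iu, iv)]
        with_entry = lookup[s][mask]
        without_entry = lookup[s][mask ^ bit]
        # with-edge state gets +sign, without-edge state gets -sign
        gid, orbits = with_entry
        totals[gid] += sign
        for node, orb in zip(st, orbits):
            key = (node, orb)
            val = entries.get(key, 0) + sign
            if val:
                entries[key] = val
            else:
                del entries[key]
        if without_entry is not None:
            gid, orbits = without_entry
            totals[gid] -= sign
            for node, orb in zip(st, orbits):
                key = (node, orb)
                val = entries.get(key, 0) - sign
                if val:
                    entries[key] = val
                else:
                    del entries[key]
    return d


def add_totals_delta(graph: Graph, u: int, v: int) -> np.ndarray:
    """Graphlet-total delta for adding (u, v); totals only, no orbit entries.

    Fast path for penalty evaluation: the per-node orbit bookkeeping (the
    bulk of :func:`delta`'s work) is skipped.  The graph is left unmodified.
    """
    if graph.has_edge(u, v):
        raise PreconditionError(f"ADD of existing edge ({u}, {v})")
    cat = taxonomy.build_catalogue()
    lookup = cat.lookup
    totals = np.zeros(N_GRAPHLETS, dtype=np.int64)
    graph.add_edge(u, v)
    try:
        adj = graph._adj
        for sub in changed_sets(graph, u, v):
            st = sorted(sub)
            s = len(st)
            mask = 0
            for rank, (i, j) in enumerate(PAIRS[s]):
                if st[j] in adj[st[i]]:
                    mask |= 1 << rank
            iu, iv = st.index(u), st.index(v)
            if iu > iv:
                iu, iv = iv, iu
            totals[lookup[s][mask][0]] += 1
            without = lookup[s][mask ^ (1 << PAIR_RANK[s][(iu, iv)])]
            if without is not None:
                totals[without[0]] -= 1
    finally:
        graph.remove_edge(u, v)
    return totals


def replay(graph: Graph, mods: Sequence[EdgeModification]):
    """Apply a stream, accumulating deltas from a full initial count.

    Returns ``(CountMatrix, GraphletTotals, final_graph)``; the input graph
    is not modified.  Raises :class:`StreamError` with the offending index
    on an invalid stream, and on any intermediate negative count.
    """
    g = graph.copy()
    cm, tot = count_all(g)
    for idx, mod in enumerate(mods):
        try:
            d = delta(g, mod)
            apply(g, mod)
        except PreconditionError as exc:
            raise StreamError(idx, str(exc)) from exc
        d.add_to(cm, tot)
        if (tot.values < 0).any():
            raise StreamError(idx, "graphlet totals went negative")
    if (cm.counts < 0).any():
        raise StreamError(len(mods) - 1, "orbit counts went negative")
    return cm, tot, g


# -- sparse delta I/O -------------------------------------------------


def write_delta(handle: TextIO, d: DeltaMatrix, labels=None, step=None):
    """Sparse TSV rows (node, orbit id, signed delta); optional step column."""
    for (node, orbit) in sorted(d.entries):
        lab = labels[node] if labels is not None else str(node)
        prefix = f"{step}\t" if step is not None else ""
        handle.write(f"{prefix}{lab}\t{orbit}\t{d.entries[(node, orbit)]}\n")
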
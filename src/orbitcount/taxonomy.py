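"""Canonical 2-5 node graphlet/orbit classification and edge-mask lookup tables.

The catalogue of the 30 connected-graph isomorphism classes on 2-5 nodes
("graphlets") and their 73 automorphism position classes ("orbits") is
*computed* rather than transcribed: every edge mask of every size is
canonicalised by permutation search, masks are grouped into isomorphism
classes, and orbits are derived from the automorphism group of each class
representative.  A shipped plain-text dump (``tests/data``) pins the result
against regressions.

Numbering convention
--------------------
* Graphlets are ordered by (size, edge count, canonical mask); ids are
  assigned sequentially, so the single edge is G0, the 3-path G1, the
  triangle G2 and the 5-clique G29.
* Orbits are numbered contiguously within each graphlet, graphlet-ordered;
  within one graphlet, orbits are sorted by (position degree, sorted
  neighbour-degree signature, smallest canonical position).  The single
  edge's orbit is O0, the 3-path has end orbit O1 and middle orbit O2, the
  triangle orbit O3 and the 5-clique orbit O72.
* Pair ranking inside an edge mask is lexicographic over 0-based position
  pairs (i, j) with i < j: for size 5 the pair (0, 1) has rank 0 and
  (3, 4) has rank 9, so bit ``1 << rank`` encodes that pair's edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Callable, Optional, Sequence

from .exceptions import DomainError

SIZES = (2, 3, 4, 5)

#: pair list / rank table per size; rank is lexicographic over (i, j), i < j
PAIRS = {s: tuple(combinations(range(s), 2)) for s in SIZES}
PAIR_RANK = {s: {p: r for r, p in enumerate(PAIRS[s])} for s in SIZES}

N_GRAPHLETS = 30
N_ORBITS = 73


class _Disconnected:
    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCONNECTED"

    def __bool__(self) -> bool:
        return False


#: sentinel classification outcome for masks that do not connect all positions
DISCONNECTED = _Disconnected()


@dataclass(frozen=True)
class GraphletClass:
    """One isomorphism class of connected graphs on 2-5 nodes."""

    id: int
    size: int
    edges: frozenset  # frozenset of (i, j) position pairs, i < j
    orbit_of_position: tuple  # orbit id per canonical position
    canonical_mask: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def redundancy(self) -> int:
        """Edges removable without disconnecting: |E| - (size - 1)."""
        return len(self.edges) - (self.size - 1)

    @property
    def orbits(self) -> tuple:
        return tuple(sorted(set(self.orbit_of_position)))


@dataclass(frozen=True)
class GraphletCatalogue:
    """The 30 graphlets, 73 orbits, and per-size classification tables."""

    graphlets: tuple  # tuple[GraphletClass]
    orbit_owner: tuple  # orbit id -> graphlet id
    # lookup[s][mask] is None (disconnected) or (graphlet id, orbit per position)
    lookup: dict = field(repr=False)

    def classify(self, mask: int, size: int):
        """Classify an edge mask: DISCONNECTED or (graphlet id, orbits)."""
        if size not in PAIRS:
            raise DomainError(f"subgraph size must be in {SIZES}, got {size}")
        table = self.lookup[size]
        if not 0 <= mask < len(table):
            raise DomainError(
                f"mask {mask} out of range [0, {len(table)}) for size {size}"
            )
        entry = table[mask]
        return DISCONNECTED if entry is None else entry

    def redundancy(self, graphlet_id: int) -> int:
        if not 0 <= graphlet_id < len(self.graphlets):
            raise DomainError(f"graphlet id {graphlet_id} out of range")
        return self.graphlets[graphlet_id].redundancy

    @property
    def n_orbits(self) -> int:
        return len(self.orbit_owner)

    def redundancy_vector(self):
        return tuple(g.redundancy for g in self.graphlets)

    def dump(self) -> str:
        """Plain-text reference dump, one graphlet per line."""
        lines = ["#id\tsize\tedges\torbits\tredundancy"]
        for g in self.graphlets:
            edges = ",".join(f"{i}-{j}" for i, j in sorted(g.edges))
            orbs = ",".join(str(o) for o in g.orbit_of_position)
            lines.append(f"{g.id}\t{g.size}\t{edges}\t{orbs}\t{g.redundancy}")
        return "\n".join(lines) + "\n"


def edge_mask(positions: Sequence, adjacent: Callable) -> int:
    """Encode the edges among ``positions`` as an integer bit mask.

    Bit ``rank(i, j)`` is set when ``adjacent(positions[i], positions[j])``
    holds; ranks are lexicographic over position-index pairs.
    """
    s = len(positions)
    if s not in PAIRS:
        raise DomainError(f"subgraph size must be in {SIZES}, got {s}")
    mask = 0
    for rank, (i, j) in enumerate(PAIRS[s]):
        if adjacent(positions[i], positions[j]):
            mask |= 1 << rank
    return mask


def _mask_edges(mask: int, size: int):
    return [PAIRS[size][r] for r in range(len(PAIRS[size])) if mask >> r & 1]


def _is_connected(mask: int, size: int) -> bool:
    adj = [[] for _ in range(size)]
    for i, j in _mask_edges(mask, size):
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == size


def _perm_bit_maps(size: int):
    """For each permutation of positions, the induced map on mask bits."""
    maps = []
    for perm in permutations(range(size)):
        bit_map = [0] * len(PAIRS[size])
        for rank, (i, j) in enumerate(PAIRS[size]):
            a, b = perm[i], perm[j]
            bit_map[rank] = PAIR_RANK[size][(a, b) if a < b else (b, a)]
        maps.append((perm, tuple(bit_map)))
    return maps


def _apply_bit_map(mask: int, bit_map) -> int:
    out = 0
    m = mask
    while m:
        r = (m & -m).bit_length() - 1
        out |= 1 << bit_map[r]
        m &= m - 1
    return out


@lru_cache(maxsize=1)
def build_catalogue() -> GraphletCatalogue:
    """Enumerate, canonicalise and orbit-partition all 2-5 node graphlets."""
    graphlets = []
    orbit_owner = []
    lookup = {}
    next_gid = 0
    next_orbit = 0

    for size in SIZES:
        n_masks = 1 << len(PAIRS[size])
        bit_maps = _perm_bit_maps(size)
        # mask -> (canonical mask, permutation achieving it)
        canon = {}
        for mask in range(n_masks):
            if not _is_connected(mask, size):
                continue
            best, best_perm = None, None
            for perm, bm in bit_maps:
                pm = _apply_bit_map(mask, bm)
                if best is None or pm < best:
                    best, best_perm = pm, perm
            canon[mask] = (best, best_perm)

        reps = sorted({c for c, _ in canon.values()})
        reps.sort(key=lambda m: (bin(m).count("1"), m))

        table = [None] * n_masks
        rep_info = {}
        for rep in reps:
            # automorphism orbits of the canonical representative
            parent = list(range(size))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for perm, bm in bit_maps:
                if _apply_bit_map(rep, bm) == rep:
                    for i in range(size):
                        ri, rj = find(i), find(perm[i])
                        if ri != rj:
                            parent[ri] = rj
            groups = {}
            for i in range(size):
                groups.setdefault(find(i), []).append(i)
            edges = _mask_edges(rep, size)
            degree = [0] * size
            for i, j in edges:
                degree[i] += 1
                degree[j] += 1
            neigh = {i: [] for i in range(size)}
            for i, j in edges:
                neigh[i].append(j)
                neigh[j].append(i)

            def orbit_key(members):
                i = min(members)
                sig = tuple(sorted(degree[u] for u in neigh[i]))
                return (degree[i], sig, i)

            ordered = sorted(groups.values(), key=orbit_key)
            orbit_of_position = [0] * size
            for local, members in enumerate(ordered):
                for i in members:
                    orbit_of_position[i] = next_orbit + local
            gid = next_gid
            rep_info[rep] = (gid, tuple(orbit_of_position))
            graphlets.append(
                GraphletClass(
                    id=gid,
                    size=size,
                    edges=frozenset(edges),
                    orbit_of_position=tuple(orbit_of_position),
                    canonical_mask=rep,
                )
            )
            orbit_owner.extend([gid] * len(ordered))
            next_gid += 1
            next_orbit += len(ordered)

        for mask, (rep, perm) in canon.items():
            gid, rep_orbits = rep_info[rep]
            # position i of `mask` maps to canonical position perm[i]
            table[mask] = (gid, tuple(rep_orbits[perm[i]] for i in range(size)))
        lookup[size] = table

    cat = GraphletCatalogue(
        graphlets=tuple(graphlets), orbit_owner=tuple(orbit_owner), lookup=lookup
    )
    assert len(cat.graphlets) == N_GRAPHLETS and cat.n_orbits == N_ORBITS
    return cat


def classify(mask: int, size: int):
    return build_catalogue().classify(mask, size)


def redundancy(graphlet_id: int) -> int:
    return build_catalogue().redundancy(graphlet_id)
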
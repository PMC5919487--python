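"""Evolving random-network generators: an initial graph plus an edge-
modification stream that keeps the instantaneous graph model-plausible.

Each step removes one existing edge and adds one absent edge, so the edge
count is invariant across the stream:

* ER — both choices uniform; the stationary graph is G(n, m).
* BA — a uniformly chosen edge is removed and one of its endpoints
  re-attached to a node sampled with probability proportional to degree,
  preserving the preferential-attachment character.
* GEO — nodes carry fixed uniform coordinates in the unit square; the
  removed edge is drawn from the few farthest present pairs and the added
  edge from the few closest absent pairs (stochastic jitter keeps streams
  seed-diverse), so present edges remain the geometrically short ones.

The exact rules are deliberately isolated behind ``generate`` so
alternative attachment/detachment schemes can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import DomainError, IntegrityError
from .graph_store import EdgeModification, Graph, Op, apply
from .incremental_counter import delta
from .static_counter import count_all

MODELS = ("ER", "BA", "GEO")
GEO_JITTER = 5  # candidate pool size for the geometric add/remove choice


@dataclass
class EvolvingNetwork:
    initial: Graph
    modifications: List[EdgeModification]
    model: str
    params: dict
    seed: int

    def final_graph(self) -> Graph:
        g = self.initial.copy()
        for m in self.modifications:
            apply(g, m)
        return g

    def sidecar(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "seed": self.seed,
            "n": self.initial.n,
            "n_modifications": len(self.modifications),
        }


def _pair_index(n: int):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return pairs


def _random_absent_pair(g: Graph, rng: np.random.Generator):
    max_edges = g.n * (g.n - 1) // 2
    if g.n_edges >= max_edges:
        raise DomainError("graph is complete; cannot add an edge")
    while True:  # rejection sampling; fine away from complete graphs
        u = int(rng.integers(g.n))
        v = int(rng.integers(g.n))
        if u != v and not g.has_edge(u, v):
            return (u, v) if u < v else (v, u)


def _random_present_edge(g: Graph, rng: np.random.Generator):
    if g.n_edges == 0:
        raise DomainError("graph has no edges; cannot remove one")
    edges = sorted(g.edges())
    return edges[int(rng.integers(len(edges)))]


def _gen_er(n: int, p: float, rng: np.random.Generator) -> Graph:
    if not 0 < p < 1:
        raise DomainError(f"ER edge probability must be in (0, 1), got {p}")
    g = Graph(n)
    upper = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if upper[i, j] < p:
                g.add_edge(i, j)
    return g


def _gen_ba(n: int, m: int, rng: np.random.Generator) -> Graph:
    if not (isinstance(m, (int, np.integer)) and 1 <= m < n):
        raise DomainError(f"BA attachment count must satisfy 1 <= m < n, got {m}")
    g = Graph(n)
    repeated: List[int] = list(range(m))  # seed pool: first m nodes
    for new in range(m, n):
        targets: set = set()
        while len(targets) < m:
            t = repeated[int(rng.integers(len(repeated)))] if repeated else int(
                rng.integers(new)
            )
            if t != new:
                targets.add(t)
        for t in targets:
            g.add_edge(new, t)
            repeated.extend((new, t))
    return g


def _gen_geo(n: int, radius: float, rng: np.random.Generator):
    if not 0 < radius < np.sqrt(2):
        raise DomainError(f"geometric radius must be in (0, sqrt(2)), got {radius}")
    coords = rng.random((n, 2))
    dists = pdist(coords)
    pairs = _pair_index(n)
    g = Graph(n)
    for (u, v), d in zip(pairs, dists):
        if d <= radius:
            g.add_edge(u, v)
    order = np.argsort(dists, kind="stable")
    return g, pairs, order


def generate(model: str, n: int, degree_param, o: int, seed: int) -> EvolvingNetwork:
    """Build an initial graph plus ``o`` modification records.

    Records come in remove-one/add-one pairs (so ``o`` must be even), keeping
    the edge count invariant across the stream.  Deterministic for a fixed
    seed; every modification is valid when applied in sequence.
    """
    if model not in MODELS:
        raise DomainError(f"unknown model {model!r}; expected one of {MODELS}")
    if n < 5:
        raise DomainError(f"need at least 5 nodes, got {n}")
    if o < 0:
        raise DomainError("number of modifications must be non-negative")
    if o % 2:
        raise DomainError(
            "modification count must be even (records come in remove/add pairs)"
        )
    rng = np.random.default_rng(seed)
    params = {"n": n, "degree_param": degree_param, "o": o}

    geo_aux = None
    if model == "ER":
        initial = _gen_er(n, degree_param, rng)
    elif model == "BA":
        initial = _gen_ba(n, degree_param, rng)
    else:
        initial, pairs, order = _gen_geo(n, degree_param, rng)
        geo_aux = (pairs, order)

    if o > 0 and (initial.n_edges == 0 or initial.n_edges >= n * (n - 1) // 2):
        raise DomainError("initial graph cannot support edge turnover")

    g = initial.copy()
    mods: List[EdgeModification] = []
    for _ in range(o // 2):
        if model == "ER":
            ru, rv = _random_present_edge(g, rng)
            au, av = _random_absent_pair_after_removal(g, rng, (ru, rv))
        elif model == "BA":
            ru, rv = _random_present_edge(g, rng)
            keep = ru if rng.random() < 0.5 else rv
            au, av = _preferential_absent(g, rng, keep, (ru, rv))
        else:
            ru, rv, au, av = _geo_step(g, rng, *geo_aux)
        mods.append(EdgeModification(Op.REMOVE, ru, rv))
        g.remove_edge(ru, rv)
        mods.append(EdgeModification(Op.ADD, au, av))
        g.add_edge(au, av)
    return EvolvingNetwork(initial, mods, model, params, seed)


def _random_absent_pair_after_removal(g, rng, removed):
    # g still holds the edge; the removed pair itself is a valid re-add target
    while True:
        u = int(rng.integers(g.n))
        v = int(rng.integers(g.n))
        if u == v:
            continue
        key = (u, v) if u < v else (v, u)
        if key == removed or not g.has_edge(u, v):
            return key


def _preferential_absent(g, rng, keep: int, removed):
    """Re-attach ``keep`` to a degree-proportional target, post-removal view."""
    weights = g.degrees().astype(float)
    ru, rv = removed
    weights[ru] -= 1
    weights[rv] -= 1
    weights[keep] = 0.0
    for v in g.neighbors(keep):
        weights[v] = 0.0
    other = rv if keep == ru else ru
    weights[other] = max(weights[other], 1e-9)  # removed partner is reattachable
    if weights.sum() <= 0:
        weights = np.ones(g.n)
        weights[keep] = 0.0
        for v in g.neighbors(keep):
            weights[v] = 0.0
        weights[other] = 1.0
    t = int(rng.choice(g.n, p=weights / weights.sum()))
    return (keep, t) if keep < t else (t, keep)


def _geo_step(g, rng, pairs, order):
    # farthest present edges (scan descending) and closest absent pairs (ascending)
    far: List = []
    for idx in order[::-1]:
        u, v = pairs[idx]
        if g.has_edge(u, v):
            far.append((u, v))
            if len(far) == GEO_JITTER:
                break
    ru, rv = far[int(rng.integers(len(far)))]
    near: List = []
    for idx in order:
        u, v = pairs[idx]
        if (u, v) == (ru, rv) or not g.has_edge(u, v):
            near.append((u, v))
            if len(near) == GEO_JITTER:
                break
    au, av = near[int(rng.integers(len(near)))]
    return ru, rv, au, av


@dataclass
class StepReport:
    step: int
    incremental_visited: int
    static_visited: int


def benchmark_replay(evolving: EvolvingNetwork, verify_every: Optional[int] = None):
    """Replay the stream through the incremental counter, recording per-step
    visited-subgraph counts for both the incremental route and the static
    recount (whose work equals the current number of connected induced
    subgraphs, tracked exactly via the totals).

    Returns a list of :class:`StepReport`.  With ``verify_every`` set, the
    accumulated counts are checked against a full static recount at those
    checkpoints; a mismatch raises :class:`IntegrityError`.
    """
    g = evolving.initial.copy()
    cm, tot = count_all(g)
    report: List[StepReport] = []
    for step, mod in enumerate(evolving.modifications):
        d = delta(g, mod)
        apply(g, mod)
        d.add_to(cm, tot)
        report.append(StepReport(step, d.visited_sets, tot.n_subgraphs))
        if verify_every and (step + 1) % verify_every == 0:
            cm_s, tot_s = count_all(g)
            if not (cm == cm_s and tot == tot_s):
                raise IntegrityError(f"checkpoint mismatch after step {step}")
    return report
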
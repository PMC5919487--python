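"""Graphlet-redundancy penalty and ranked-edge network growth.

The redundancy penalty of a network is the sum over graphlet classes of
(occurrences x redundancy), where a graphlet's redundancy is the number of
edges removable without disconnecting it.  Densely interconnected clusters
— where inferred regulatory networks concentrate false positives — score
high; tree-like structure scores zero.

``grow`` rebuilds a network from an empty graph by walking a ranked
candidate-edge list: each iteration scores the next k not-yet-accepted
candidates by their incremental penalty increase and accepts the
highest-ranked one strictly below the window's 90th-percentile increase
(nearest-rank percentile; fallback to the minimum-increase, highest-ranked
candidate when nothing passes).  The acceptance order is the reranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, TextIO, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import taxonomy
from .exceptions import DomainError, ParseError, PreconditionError, UndefinedMetricError
from .graph_store import EdgeModification, Graph, Op
from .incremental_counter import add_totals_delta, delta
from .static_counter import GraphletTotals


@dataclass
class RankedEdge:
    source: str
    target: str
    score: float

    @property
    def pair(self) -> Tuple[str, str]:
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


@dataclass
class RankedEdgeList:
    """Score-descending candidate interactions with no duplicate pairs.

    Directed input pairs are canonicalised to unordered pairs; on duplicates
    the best-scoring (earliest) record wins.
    """

    records: List[RankedEdge]

    def __post_init__(self):
        seen: Set[Tuple[str, str]] = set()
        kept = []
        for r in self.records:
            if r.source == r.target:
                raise DomainError(f"self-interaction {r.source!r}")
            if r.pair in seen:
                continue
            seen.add(r.pair)
            kept.append(r)
        for a, b in zip(kept, kept[1:]):
            if b.score > a.score:
                raise DomainError("scores must be non-increasing")
        self.records = kept

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> List[Tuple[str, str]]:
        return [r.pair for r in self.records]

    def labels(self) -> List[str]:
        out: List[str] = []
        seen: Set[str] = set()
        for r in self.records:
            for lab in (r.source, r.target):
                if lab not in seen:
                    seen.add(lab)
                    out.append(lab)
        return out


@dataclass
class OptimiserConfig:
    k: int = 100
    percentile: float = 90.0
    budget: Optional[int] = None  # max accepted edges; None = whole list

    def __post_init__(self):
        if self.k < 1:
            raise DomainError("candidate window k must be >= 1")
        if not 0 < self.percentile < 100:
            raise DomainError("percentile must lie strictly between 0 and 100")


def redundancy_penalty(totals: GraphletTotals) -> int:
    """Sum over graphlets of occurrences x redundancy."""
    cat = taxonomy.build_catalogue()
    red = np.array(cat.redundancy_vector(), dtype=np.int64)
    return int(totals.values @ red)


def _redundancy_vector() -> np.ndarray:
    return np.array(taxonomy.build_catalogue().redundancy_vector(), dtype=np.int64)


def penalty_increase(graph: Graph, u: int, v: int) -> int:
    """Penalty delta from adding (u, v), computed incrementally, no mutation."""
    if graph.has_edge(u, v):
        raise PreconditionError(f"candidate edge ({u}, {v}) already present")
    return int(add_totals_delta(graph, u, v) @ _redundancy_vector())


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    ordered = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[rank - 1]


def grow(ranked: RankedEdgeList, config: Optional[OptimiserConfig] = None):
    """Grow a network from empty by percentile-gated greedy acceptance.

    Returns ``(graph, labels, accepted)`` where ``accepted`` is the
    acceptance-ordered list of :class:`RankedEdge` records (a permutation of
    a prefix-heavy subset of the input).
    """
    if config is None:
        config = OptimiserConfig()
    if len(ranked) == 0:
        raise DomainError("ranked edge list is empty")
    labels = ranked.labels()
    index = {lab: i for i, lab in enumerate(labels)}
    g = Graph(len(labels))
    remaining = list(ranked.records)
    accepted: List[RankedEdge] = []
    budget = config.budget if config.budget is not None else len(remaining)
    # increase cache: a candidate's increase only changes when an accepted
    # edge lands in its 5-node-subgraph reach, so invalidate by locality
    cache: Dict[Tuple[str, str], int] = {}
    while remaining and len(accepted) < budget:
        window = remaining[: config.k]
        increases = []
        for r in window:
            inc = cache.get(r.pair)
            if inc is None:
                inc = penalty_increase(g, index[r.source], index[r.target])
                cache[r.pair] = inc
            increases.append(inc)
        gate = nearest_rank_percentile(increases, config.percentile)
        choice = None
        for pos, inc in enumerate(increases):
            if inc < gate:
                choice = pos
                break
        if choice is None:  # degenerate window: take min increase, best rank
            choice = min(range(len(window)), key=lambda p: (increases[p], p))
        rec = remaining.pop(choice)
        g.add_edge(index[rec.source], index[rec.target])
        accepted.append(rec)
        ball = _reach_ball(g, index[rec.source], index[rec.target])
        cache = {
            pair: inc
            for pair, inc in cache.items()
            if index[pair[0]] not in ball and index[pair[1]] not in ball
        }
    return g, labels, accepted


def _reach_ball(g: Graph, a: int, b: int, radius: int = 4) -> Set[int]:
    """Nodes within ``radius`` hops of either endpoint (cache invalidation)."""
    frontier = {a, b}
    ball = {a, b}
    for _ in range(radius):
        nxt = set()
        for u in frontier:
            nxt |= g.neighbors(u)
        nxt -= ball
        if not nxt:
            break
        ball |= nxt
        frontier = nxt
    return ball


def evaluate_f1(
    ranked: RankedEdgeList,
    gold_positives: Set[Tuple[str, str]],
    universe: Optional[Set[Tuple[str, str]]] = None,
    top: int = 1000,
) -> Tuple[float, float, float]:
    """AUROC, AUPR and their harmonic mean over the first ``top`` records.

    Positives are the gold pairs present among the truncated records;
    the remaining truncated records are the negatives.
    """
    if top < 1:
        raise DomainError("top must be >= 1")
    if top > len(ranked):
        raise DomainError(f"top={top} exceeds ranked-list length {len(ranked)}")
    gold = {tuple(sorted(p)) for p in gold_positives}
    if universe is not None:
        uni = {tuple(sorted(p)) for p in universe}
        if not gold <= uni:
            raise DomainError("gold positives must be a subset of the universe")
        if not gold & uni:
            raise UndefinedMetricError("no gold positives in the universe")
    records = ranked.records[:top]
    y_true = np.array([1 if r.pair in gold else 0 for r in records])
    y_score = np.array([r.score for r in records], dtype=float)
    if y_true.sum() == 0:
        raise UndefinedMetricError("no gold positives among the ranked pairs")
    if y_true.sum() == len(y_true):
        raise UndefinedMetricError("no negatives among the ranked pairs")
    auroc = float(roc_auc_score(y_true, y_score))
    aupr = float(average_precision_score(y_true, y_score))
    f1 = 0.0 if auroc + aupr == 0 else 2 * auroc * aupr / (auroc + aupr)
    return auroc, aupr, f1


def rerank_scores(accepted: List[RankedEdge]) -> RankedEdgeList:
    """Turn an acceptance order into a valid ranked list (rank-based scores)."""
    n = len(accepted)
    return RankedEdgeList(
        [
            RankedEdge(r.source, r.target, float(n - i))
            for i, r in enumerate(accepted)
        ]
    )


# -- I/O --------------------------------------------------------------


def read_ranked(handle: TextIO) -> RankedEdgeList:
    """TSV (source, target, score); descending score enforced."""
    records = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 3:
            raise ParseError(lineno, f"expected 3 columns, got {len(toks)}")
        try:
            score = float(toks[2])
        except ValueError as exc:
            raise ParseError(lineno, f"bad score {toks[2]!r}") from exc
        if not math.isfinite(score):
            raise ParseError(lineno, f"non-finite score {toks[2]!r}")
        records.append(RankedEdge(toks[0], toks[1], score))
    try:
        return RankedEdgeList(records)
    except DomainError as exc:
        raise ParseError(0, str(exc)) from exc


def write_ranked(handle: TextIO, ranked) -> None:
    records = ranked.records if isinstance(ranked, RankedEdgeList) else ranked
    for r in records:
        handle.write(f"{r.source}\t{r.target}\t{r.score:.6g}\n")


def read_gold(handle: TextIO) -> Set[Tuple[str, str]]:
    """Two-column TSV of known interactions."""
    gold = set()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 2:
            raise ParseError(lineno, f"expected 2 columns, got {len(toks)}")
        if toks[0] == toks[1]:
            raise ParseError(lineno, f"self-interaction {toks[0]!r}")
        gold.add(tuple(sorted(toks[:2])))
    return gold
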
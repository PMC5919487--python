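import io
import random

import numpy as np
import pytest

from orbitcount.exceptions import (
    DomainError,
    ParseError,
    PreconditionError,
    UndefinedMetricError,
)
from orbitcount.fixtures import planted_grn
from orbitcount.graph_store import Graph
from orbitcount.redundancy_optimiser import (
    OptimiserConfig,
    RankedEdge,
    RankedEdgeList,
    evaluate_f1,
    grow,
    nearest_rank_percentile,
    penalty_increase,
    read_gold,
    read_ranked,
    redundancy_penalty,
    rerank_scores,
    write_ranked,
)
from orbitcount.static_counter import count_all
from conftest import random_er_graph


class TestRankedEdgeList:
    def test_directed_duplicates_collapse(self):
        rl = RankedEdgeList(
            [RankedEdge("a", "b", 3.0), RankedEdge("b", "a", 2.0), RankedEdge("a", "c", 1.0)]
        )
        assert len(rl) == 2
        assert rl.records[0].score == 3.0

    def test_increasing_scores_rejected(self):
        with pytest.raises(DomainError):
            RankedEdgeList([RankedEdge("a", "b", 1.0), RankedEdge("a", "c", 2.0)])

    def test_self_interaction_rejected(self):
        with pytest.raises(DomainError):
            RankedEdgeList([RankedEdge("a", "a", 1.0)])


class TestPenalty:
    def test_forest_zero(self):
        g = Graph.from_edges(7, [(0, 1), (1, 2), (3, 4), (4, 5), (5, 6)])
        assert redundancy_penalty(count_all(g)[1]) == 0

    def test_single_triangle(self, triangle):
        assert redundancy_penalty(count_all(triangle)[1]) == 1

    def test_k4(self):
        g = Graph.from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert redundancy_penalty(count_all(g)[1]) == 7


class TestPenaltyIncrease:
    def test_joining_components_is_free(self):
        # two disjoint 2-paths; bridging them creates only tree graphlets
        g = Graph.from_edges(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        assert penalty_increase(g, 2, 3) == 0

    def test_closing_triangle(self):
        g = Graph.from_edges(3, [(0, 1), (1, 2)])
        assert penalty_increase(g, 0, 2) == 1

    def test_k5_final_edge_matches_static_difference(self, k5):
        g = k5
        g.remove_edge(0, 1)
        before = redundancy_penalty(count_all(g)[1])
        inc = penalty_increase(g, 0, 1)
        g.add_edge(0, 1)
        after = redundancy_penalty(count_all(g)[1])
        assert inc == after - before

    def test_present_edge_rejected(self, triangle):
        with pytest.raises(PreconditionError):
            penalty_increase(triangle, 0, 1)

    def test_no_mutation(self):
        g = Graph.from_edges(3, [(0, 1), (1, 2)])
        penalty_increase(g, 0, 2)
        assert not g.has_edge(0, 2)

    def test_path_independence(self):
        """Accumulated increases equal the static penalty for any build order."""
        rng = random.Random(51)
        for _ in range(8):
            n = rng.randint(6, 15)
            g_full = random_er_graph(rng, n, 0.35)
            edges = sorted(g_full.edges())
            static = redundancy_penalty(count_all(g_full)[1])
            for _ in range(20):
                order = edges[:]
                rng.shuffle(order)
                g = Graph(n)
                acc = 0
                for u, v in order:
                    acc += penalty_increase(g, u, v)
                    g.add_edge(u, v)
                assert acc == static


class TestPercentile:
    def test_nearest_rank(self):
        vals = [0, 0, 0, 0, 0, 0, 0, 0, 0, 5]
        assert nearest_rank_percentile(vals, 90) == 0
        assert nearest_rank_percentile(vals, 95) == 5
        assert nearest_rank_percentile([7], 90) == 7


class TestGrow:
    def test_all_tree_like_keeps_rank_order(self):
        records = [
            RankedEdge(f"a{i}", f"b{i}", float(10 - i)) for i in range(6)
        ]
        rl = RankedEdgeList(records)
        _, _, accepted = grow(rl, OptimiserConfig(k=3))
        assert [r.pair for r in accepted] == [r.pair for r in records]

    def test_clique_closer_deferred(self):
        """A candidate closing a dense clique loses to a component-joining one."""
        # build K4 on a..d first (all tree-ish/low increase up front), then
        # offer the K4-diagonal-completing edge vs a fresh bridge
        records = [
            RankedEdge("a", "b", 10.0),
            RankedEdge("b", "c", 9.0),
            RankedEdge("c", "d", 8.0),
            RankedEdge("d", "a", 7.0),
            RankedEdge("a", "c", 6.0),
            RankedEdge("b", "d", 5.0),  # completes K4: high increase
            RankedEdge("x", "y", 4.0),  # disjoint edge: zero increase
        ]
        rl = RankedEdgeList(records)
        _, _, accepted = grow(rl, OptimiserConfig(k=2))
        order = [r.pair for r in accepted]
        assert order.index(("x", "y")) < order.index(("b", "d"))

    def test_budget_limits_acceptance(self):
        rl = RankedEdgeList([RankedEdge(f"a{i}", f"b{i}", float(9 - i)) for i in range(5)])
        g, labels, accepted = grow(rl, OptimiserConfig(budget=1))
        assert len(accepted) == 1 and g.n_edges == 1

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            grow(RankedEdgeList([]))

    def test_reranking_is_permutation_of_prefix_subset(self):
        ranked, gold, _ = planted_grn(n=40, seed=0, n_noise=40)
        _, _, accepted = grow(ranked, OptimiserConfig(k=20, budget=30))
        pairs = [r.pair for r in accepted]
        assert len(set(pairs)) == len(pairs)
        assert set(pairs) <= set(ranked.pairs())


class TestEvaluateF1:
    def _make(self, n=60):
        return RankedEdgeList(
            [RankedEdge(f"a{i}", f"b{i}", float(n - i)) for i in range(n)]
        )

    def test_perfect_ranking(self):
        rl = self._make()
        gold = {(f"a{i}", f"b{i}") for i in range(20)}
        auroc, aupr, f1 = evaluate_f1(rl, gold, top=60)
        assert auroc == 1.0
        assert aupr == pytest.approx(1.0)
        assert f1 == pytest.approx(1.0)

    def test_inverted_ranking(self):
        rl = self._make()
        gold = {(f"a{i}", f"b{i}") for i in range(40, 60)}
        auroc, _, _ = evaluate_f1(rl, gold, top=60)
        assert auroc == 0.0

    def test_random_ranking_near_half(self):
        rng = random.Random(61)
        n = 2000
        rl = self._make(n)
        gold = {(f"a{i}", f"b{i}") for i in rng.sample(range(n), 600)}
        auroc, _, _ = evaluate_f1(rl, gold, top=n)
        assert abs(auroc - 0.5) < 0.05

    def test_truncation_matters(self):
        rl = self._make(50)
        gold = {(f"a{i}", f"b{i}") for i in range(5)} | {("a49", "b49")}
        full = evaluate_f1(rl, gold, top=50)
        head = evaluate_f1(rl, gold, top=10)
        assert head[0] == 1.0 and full[0] < 1.0

    def test_error_cases(self):
        rl = self._make(10)
        with pytest.raises(UndefinedMetricError):
            evaluate_f1(rl, set(), top=10)
        with pytest.raises(UndefinedMetricError):
            evaluate_f1(rl, {(f"a{i}", f"b{i}") for i in range(10)}, top=10)
        with pytest.raises(DomainError):
            evaluate_f1(rl, {("a0", "b0")}, top=11)
        with pytest.raises(DomainError):
            evaluate_f1(rl, {("zz", "zq")}, universe={("a0", "b0")}, top=5)

    def test_harmonic_mean(self):
        rl = RankedEdgeList(
            [
                RankedEdge("a", "b", 4.0),
                RankedEdge("c", "d", 3.0),
                RankedEdge("e", "f", 2.0),
                RankedEdge("g", "h", 1.0),
            ]
        )
        gold = {("a", "b"), ("e", "f")}
        auroc, aupr, f1 = evaluate_f1(rl, gold, top=4)
        assert f1 == pytest.approx(2 * auroc * aupr / (auroc + aupr))


class TestDirectionalImprovement:
    def test_reranking_tends_to_help(self):
        """Light version of the acceptance run: 5 seeds, small fixture."""
        wins = 0
        for seed in range(5):
            ranked, gold, _ = planted_grn(n=60, seed=seed, n_noise=80)
            top = 90
            raw = evaluate_f1(ranked, gold, top=top)[2]
            _, _, accepted = grow(ranked, OptimiserConfig(k=60, budget=top))
            rer = evaluate_f1(rerank_scores(accepted), gold, top=top)[2]
            wins += rer >= raw
        assert wins >= 4


class TestIO:
    def test_ranked_round_trip(self):
        rl = RankedEdgeList(
            [RankedEdge("a", "b", 2.5), RankedEdge("c", "d", 1.25)]
        )
        buf = io.StringIO()
        write_ranked(buf, rl)
        buf.seek(0)
        rl2 = read_ranked(buf)
        assert [(r.source, r.target, r.score) for r in rl2.records] == [
            ("a", "b", 2.5),
            ("c", "d", 1.25),
        ]

    def test_bad_score_column(self):
        with pytest.raises(ParseError) as exc:
            read_ranked(io.StringIO("a\tb\tnot_a_number\n"))
        assert exc.value.line == 1

    def test_gold_reader(self):
        gold = read_gold(io.StringIO("# known\nb\ta\nc\td\n"))
        assert gold == {("a", "b"), ("c", "d")}
        with pytest.raises(ParseError):
            read_gold(io.StringIO("a\ta\n"))
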
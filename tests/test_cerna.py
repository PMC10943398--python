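"""Hypergeometric sharing test, co-expression filter, network assembly, hubs."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cuprosep import (
    build_cerna_network,
    coexpression_pcc,
    hypergeom_competing_test,
    rank_hubs,
    simulate_interactions,
)
from cuprosep.containers import InteractionTable
from cuprosep.errors import ArgumentError, DataError


def hypergeom_tail_oracle(N, n, m, x, at_least=False):
    """Brute-force pmf summation of the shared-miRNA null distribution."""
    def pmf(k):
        if k > m or k > n or n - k > N - m:
            return 0.0
        return math.comb(m, k) * math.comb(N - m, n - k) / math.comb(N, n)

    lo = x if at_least else x + 1
    return sum(pmf(k) for k in range(lo, min(n, m) + 1))


def interaction_table(edges, kind):
    return InteractionTable(
        pd.DataFrame(
            {"mirna_id": [m for m, _ in edges], "target_id": [t for _, t in edges],
             "target_kind": kind}
        )
    )


class TestHypergeomTest:
    def test_worked_values(self):
        assert hypergeom_competing_test(10, 3, 4, 2, "as_printed") == pytest.approx(4 / 120, abs=1e-12)
        assert hypergeom_competing_test(10, 3, 4, 2, "at_least_x") == pytest.approx(40 / 120, abs=1e-12)

    def test_maximal_overlap_as_printed_zero(self):
        assert hypergeom_competing_test(20, 5, 8, 5, "as_printed") == 0.0

    def test_matches_enumeration_small_universe(self):
        for N in range(1, 13):
            for n in range(N + 1):
                for m in range(N + 1):
                    for x in range(min(n, m) + 1):
                        p1 = hypergeom_competing_test(N, n, m, x, "as_printed")
                        p2 = hypergeom_competing_test(N, n, m, x, "at_least_x")
                        assert p1 == pytest.approx(hypergeom_tail_oracle(N, n, m, x), abs=1e-12)
                        assert p2 == pytest.approx(hypergeom_tail_oracle(N, n, m, x, True), abs=1e-12)

    def test_conventions_ordered(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(n, m) + 1))
            assert hypergeom_competing_test(N, n, m, x, "as_printed") <= (
                hypergeom_competing_test(N, n, m, x, "at_least_x") + 1e-15
            )

    @pytest.mark.parametrize("args", [(-1, 0, 0, 0), (5, 6, 2, 1), (5, 2, 2, 3)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ArgumentError):
            hypergeom_competing_test(*args)


class TestCoexpression:
    def test_identity_gives_one(self):
        x = np.arange(6.0)
        r, _ = coexpression_pcc(x, x)
        assert r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # duplicated form of the classic 3-point pattern; same correlation
        r, _ = coexpression_pcc([1, 2, 3, 1, 2, 3], [1, 3, 2, 1, 3, 2])
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_affine_anticorrelation(self):
        x = np.arange(8.0)
        r, _ = coexpression_pcc(x, -2 * x + 7)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(DataError):
            coexpression_pcc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            coexpression_pcc([1, 2, 3], [1, 3, 2])


class TestBuildNetwork:
    def test_empty_tables_give_empty_outputs(self):
        mt = interaction_table([], "mRNA")
        lt = interaction_table([], "lncRNA")
        expr = pd.DataFrame(np.zeros((5, 0)), index=[f"s{i}" for i in range(5)])
        cand, G = build_cerna_network(mt, lt, expr, {"GENE"})
        assert cand == [] and len(G) == 0

    def test_planted_pair_retained_and_assembled(self):
        """One pair sharing 2 of a 6-miRNA universe with strong co-expression."""
        mirnas = [f"mi{j}" for j in range(6)]
        mt = interaction_table([(mirnas[0], "M"), (mirnas[1], "M"), (mirnas[2], "M")], "mRNA")
        lt = interaction_table([(mirnas[0], "L"), (mirnas[1], "L")], "lncRNA")
        # pad universe to 6 distinct miRNAs via extra background targets
        mt2 = interaction_table(
            mt.edges[["mirna_id", "target_id"]].values.tolist()
            + [(mirnas[3], "M2"), (mirnas[4], "M2"), (mirnas[5], "M2")],
            "mRNA",
        )
        rng = np.random.default_rng(0)
        base = rng.normal(size=40)
        expr = pd.DataFrame(
            {"M": base, "L": 0.9 * base + 0.1 * rng.normal(size=40),
             "M2": rng.normal(size=40)},
            index=[f"s{i}" for i in range(40)],
        )
        cand, G = build_cerna_network(mt2, lt, expr, {"M"})
        assert len(cand) == 1
        c = cand[0]
        assert (c.N, c.n, c.m, c.x) == (6, 3, 2, 2)
        assert c.p_hyper == 0.0  # x = min(n, m): upper tail empty
        assert c.retained
        assert set(G.nodes) == {"L", "M", "mi0", "mi1"}

    def test_uncorrelated_pair_not_retained(self):
        """Perfect sharing is not enough without co-expression."""
        for seed in range(20):
            mt, lt, truth, expr = simulate_interactions(
                30, 5, 5, 1, 10, 0.0, seed=seed, planted_pcc=0.9
            )
            lnc, mrna = truth.planted_pairs[0]
            rng = np.random.default_rng(10_000 + seed)
            expr[lnc] = rng.normal(size=len(expr))  # break the co-expression
            cand, _ = build_cerna_network(mt, lt, expr, {mrna})
            c = [c for c in cand if (c.lncrna, c.mrna) == (lnc, mrna)][0]
            assert c.p_hyper < 0.01 and not c.retained

    def test_planted_pairs_beat_background(self):
        """Planted pairs' sharing p is far below random background pairs'."""
        mt, lt, truth, expr = simulate_interactions(200, 30, 40, 5, 20, 0.02, seed=3)
        N = len(mt.mirnas | lt.mirnas)
        planted_p = []
        for lnc, mrna in truth.planted_pairs:
            n, m = len(mt.mirnas_of(mrna)), len(lt.mirnas_of(lnc))
            x = len(mt.mirnas_of(mrna) & lt.mirnas_of(lnc))
            planted_p.append(hypergeom_competing_test(N, n, m, x))
        rng = np.random.default_rng(0)
        mrnas = mt.targets("mRNA")
        lncs = lt.targets("lncRNA")
        planted = set(truth.planted_pairs)
        bg_p = []
        while len(bg_p) < 100:
            pair = (lncs[rng.integers(len(lncs))], mrnas[rng.integers(len(mrnas))])
            if pair in planted:
                continue
            n = len(mt.mirnas_of(pair[1]))
            m = len(lt.mirnas_of(pair[0]))
            x = len(mt.mirnas_of(pair[1]) & lt.mirnas_of(pair[0]))
            bg_p.append(hypergeom_competing_test(N, n, m, x))
        assert np.median(planted_p) < np.median(bg_p)

    def test_missing_key_gene_logged_not_fatal(self, caplog):
        mt = interaction_table([("mi0", "M")], "mRNA")
        lt = interaction_table([("mi0", "L")], "lncRNA")
        expr = pd.DataFrame({"M": np.arange(5.0), "L": np.arange(5.0)},
                            index=[f"s{i}" for i in range(5)])
        cand, _ = build_cerna_network(mt, lt, expr, {"M", "ABSENT"})
        assert len(cand) == 1


def betweenness_oracle(G):
    """Path-enumeration betweenness: count shortest paths through each node."""
    bc = {v: 0.0 for v in G}
    nodes = list(G)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(G, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


class TestRankHubs:
    def _annotated(self, G):
        from cuprosep.cerna import _annotate

        _annotate(G)
        return G

    def test_star_center_is_hub(self):
        G = nx.star_graph(5)
        G = nx.relabel_nodes(G, {0: "hub", **{i: f"mi{i}" for i in range(1, 6)}})
        nx.set_node_attributes(G, "miRNA", "kind")
        G.nodes["hub"]["kind"] = "lncRNA"
        hubs = rank_hubs(self._annotated(G))
        assert hubs[0] == ("hub", 5, 10.0)

    def test_path_graph_betweenness(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        nx.set_node_attributes(G, "lncRNA", "kind")
        hubs = dict((h[0], h[2]) for h in rank_hubs(self._annotated(G)))
        assert hubs == {"a": 0.0, "b": 2.0, "c": 2.0, "d": 0.0}

    def test_betweenness_breaks_degree_ties(self):
        G = nx.Graph([("L1", "x"), ("L1", "y"), ("L2", "y"), ("L2", "z"), ("x", "w"), ("z", "w")])
        nx.set_node_attributes(G, "miRNA", "kind")
        G.nodes["L1"]["kind"] = G.nodes["L2"]["kind"] = "lncRNA"
        hubs = rank_hubs(self._annotated(G))
        oracle = betweenness_oracle(G)
        assert [h[0] for h in hubs] == sorted(
            ["L1", "L2"], key=lambda v: (-G.degree[v], -oracle[v], v)
        )

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=int(rng.integers(1e6)))
            bc = nx.betweenness_centrality(G, normalized=False)
            oracle = betweenness_oracle(G)
            for v in G:
                assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_no_lncrna_nodes_gives_empty_list(self):
        G = nx.Graph([("a", "b")])
        nx.set_node_attributes(G, "miRNA", "kind")
        assert rank_hubs(self._annotated(G)) == []
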
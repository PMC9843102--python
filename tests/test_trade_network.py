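"""Top-k/tie network construction and weighted PageRank centrality."""

import numpy as np
import pytest

from marisk import (
    SymmetricMatrix,
    TradeNetwork,
    build_network,
    pagerank,
    rank_centrality,
    top_partners,
)
from tests.conftest import dense_pagerank_oracle, random_connectivity, random_digraph, random_times


def star_conn(center, partners):
    conn = SymmetricMatrix()
    for p, w in partners.items():
        conn.set(center, p, w)
    return conn


class TestBuildNetwork:
    def test_three_way_tie_at_top_value_yields_three_edges(self):
        conn = star_conn("SDN", {"EGY": 0.5, "KEN": 0.5, "MAR": 0.5, "XXX": 0.2})
        net = build_network(conn, k=3)
        assert {v for (u, v) in net.edges if u == "SDN"} == {"EGY", "KEN", "MAR"}

    def test_tie_at_kth_value_extends_out_degree(self):
        conn = star_conn("AAA", {"BBB": 0.9, "CCC": 0.5, "DDD": 0.5, "EEE": 0.5})
        net = build_network(conn, k=3)
        assert {v for (u, v) in net.edges if u == "AAA"} == {"BBB", "CCC", "DDD", "EEE"}

    def test_fewer_partners_than_k(self):
        conn = star_conn("AAA", {"BBB": 0.4, "CCC": 0.2})
        net = build_network(conn, k=3)
        assert len([1 for (u, _) in net.edges if u == "AAA"]) == 2

    def test_zero_lsbci_pairs_are_ineligible(self):
        conn = star_conn("AAA", {"BBB": 0.4, "CCC": 0.0})
        net = build_network(conn, k=3)
        assert ("AAA", "CCC") not in net.edges

    def test_cutoff_filters_before_topk_selection(self):
        # AAA's three best partners are all beyond the cutoff; the 4th-best
        # (weaker but reachable) must still receive the link.
        conn = star_conn("AAA", {"BBB": 0.9, "CCC": 0.8, "DDD": 0.7, "EEE": 0.3})
        times = SymmetricMatrix()
        for p, d in {"BBB": 20.0, "CCC": 25.0, "DDD": 30.0, "EEE": 5.0}.items():
            times.set("AAA", p, d)
        net = build_network(conn, k=3, max_days=14.0, times=times)
        assert {v for (u, v) in net.edges if u == "AAA"} == {"EEE"}

    def test_infinite_cutoff_equals_unrestricted(self, small_bundle):
        b = small_bundle
        unrestricted = build_network(b.conn, k=3)
        cutoff = build_network(b.conn, k=3, max_days=float("inf"), times=b.times)
        assert unrestricted.edges == cutoff.edges

    def test_tightening_cutoff_never_adds_eligible_partners(self, small_bundle):
        b = small_bundle
        def eligible(max_days):
            net = build_network(b.conn, k=len(b.conn.countries()), max_days=max_days,
                                times=b.times)
            return set(net.edges)
        wide, narrow = eligible(30.0), eligible(10.0)
        assert narrow <= wide

    def test_in_degree_attribute_matches_incoming_edges(self, small_bundle):
        net = build_network(small_bundle.conn, k=3)
        for node in net.nodes:
            assert net.in_degree(node) == sum(1 for (_, v) in net.edges if v == node)

    def test_parameter_validation(self, small_bundle):
        with pytest.raises(ValueError, match="k"):
            build_network(small_bundle.conn, k=0)
        with pytest.raises(ValueError, match="transit-time"):
            build_network(small_bundle.conn, k=3, max_days=14.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_topk_law_against_counting_oracle(self, seed):
        """Partner v gets an edge iff fewer than k eligible partners beat it."""
        conn = random_connectivity(seed)
        k = 3
        net = build_network(conn, k=k)
        nodes = conn.countries()
        for u in nodes:
            elig = {v: conn.get(u, v) for v in nodes
                    if v != u and (conn.get(u, v) or 0) > 0}
            expected = {v for v, w in elig.items()
                        if sum(1 for w2 in elig.values() if w2 > w) < k}
            assert {v for (a, v) in net.edges if a == u} == expected
            out_deg = len(expected)
            assert min(k, len(elig)) <= out_deg <= len(elig)


class TestPagerank:
    def test_two_mutual_nodes_split_evenly(self):
        net = TradeNetwork(nodes=("AAA", "BBB"),
                           edges={("AAA", "BBB"): 0.7, ("BBB", "AAA"): 0.7}, k=3)
        r = pagerank(net)
        assert r.scores["AAA"] == pytest.approx(0.5, abs=1e-12)
        assert r.scores["BBB"] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 6, 9])
    def test_directed_ring_is_uniform(self, n):
        nodes = tuple(f"N{i}" for i in range(n))
        edges = {(nodes[i], nodes[(i + 1) % n]): 0.4 for i in range(n)}
        r = pagerank(TradeNetwork(nodes=nodes, edges=edges, k=3))
        for v in r.scores.values():
            assert v == pytest.approx(1.0 / n, abs=1e-9)

    def test_node_without_inflow_sits_at_teleport_floor(self):
        # AAA points into a cycle but nothing points back at it, and no
        # node dangles, so AAA holds exactly the teleport mass.
        nodes = ("AAA", "BBB", "CCC")
        edges = {("AAA", "BBB"): 0.5, ("BBB", "CCC"): 0.5, ("CCC", "BBB"): 0.5}
        r = pagerank(TradeNetwork(nodes=nodes, edges=edges, k=3), damping=0.85)
        assert r.scores["AAA"] == pytest.approx(0.15 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_google_matrix_oracle(self, seed):
        net = random_digraph(seed)
        r = pagerank(net, tol=1e-14)
        oracle = dense_pagerank_oracle(net)
        for c in net.nodes:
            assert r.scores[c] == pytest.approx(oracle[c], abs=1e-8)

    def test_dangling_nodes_conserve_probability(self):
        net = random_digraph(3, force_dangling=True)
        r = pagerank(net)
        assert sum(r.scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert min(r.scores.values()) >= (1 - r.damping) / net.n - 1e-12

    def test_parameter_validation(self):
        net = random_digraph(0)
        with pytest.raises(ValueError, match="damping"):
            pagerank(net, damping=1.5)
        with pytest.raises(ValueError, match="tol"):
            pagerank(net, tol=0.0)


class TestPartnerAndCentralityRankings:
    def test_top_partners_sorted_by_weight(self):
        net = TradeNetwork(
            nodes=("DJI", "SDN", "EGY", "KEN"),
            edges={("DJI", "SDN"): 0.6, ("DJI", "EGY"): 0.4, ("DJI", "KEN"): 0.3},
            k=3,
        )
        assert [c for c, _ in top_partners(net, "DJI")] == ["SDN", "EGY", "KEN"]

    def test_isolated_node_has_no_partners(self):
        net = TradeNetwork(nodes=("AAA", "BBB"), edges={}, k=3)
        assert top_partners(net, "AAA") == []

    def test_unknown_country_is_a_lookup_error(self):
        net = TradeNetwork(nodes=("AAA",), edges={}, k=3)
        with pytest.raises(KeyError):
            top_partners(net, "ZZZ")

    def test_planted_strongest_links_recovered_in_order(self):
        conn = star_conn("HUB", {"AAA": 0.9, "BBB": 0.8, "CCC": 0.7, "DDD": 0.1})
        net = build_network(conn, k=3)
        assert [c for c, _ in top_partners(net, "HUB")] == ["AAA", "BBB", "CCC"]

    def test_rank_centrality_orders_and_breaks_ties_alphabetically(self):
        from marisk.trade_network import CentralityResult
        result = CentralityResult(scores={"AAA": 0.5, "CCC": 0.2, "BBB": 0.2, "DDD": 0.1},
                                  damping=0.85, iterations=10, converged=True)
        ranked = rank_centrality(result)
        assert [(c, r) for c, _, r in ranked] == [
            ("AAA", 1), ("BBB", 2), ("CCC", 3), ("DDD", 4)]

    def test_centrality_ordering_agrees_with_dense_oracle(self):
        rng_net = random_digraph(123, max_n=10)
        r = pagerank(rng_net, tol=1e-14)
        oracle = dense_pagerank_oracle(rng_net)
        ours = [c for c, _, _ in rank_centrality(r)]
        theirs = sorted(oracle, key=lambda c: (-oracle[c], c))
        assert ours == theirs
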
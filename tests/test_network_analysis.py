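"""Graph construction, filtering, communities, categories, differentials."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import peel_kcore
from ringnet.network_analysis import (CommunityPartition, RingNetwork,
                                      build_graph, cross_community_edges,
                                      detect_communities, differential_edges,
                                      edge_categories, filter_graph,
                                      node_strengths, write_community_tsv,
                                      write_graphml)
from ringnet.pairwise_correlation import RingSet


def ringset_from_edges(edges, length=2000):
    """edges: iterable of (i, j, phi)."""
    rows = [{"i": i, "j": j, "n11": 1, "n10": 1, "n01": 1, "n00": 1,
             "depth": 4, "chi2": 25.0, "phi": phi} for i, j, phi in edges]
    df = pd.DataFrame(rows, columns=["i", "j", "n11", "n10", "n01", "n00",
                                     "depth", "chi2", "phi"])
    return RingSet(rings=df, length=length)


def network_from_edges(edges):
    return build_graph(ringset_from_edges(edges))


class TestBuildGraph:
    def test_nodes_edges_and_weights(self):
        g = network_from_edges([(1, 2, 0.05), (2, 3, -0.02), (3, 4, 0.1)])
        assert g.n_nodes == 4 and g.n_edges == 3
        assert g.graph.edges[2, 3]["weight"] == pytest.approx(0.02)
        assert g.graph.edges[2, 3]["sign"] == -1
        assert g.graph.edges[1, 2]["sign"] == 1

    def test_duplicate_pairs_rejected_upstream(self):
        with pytest.raises(ValueError):
            ringset_from_edges([(1, 2, 0.05), (1, 2, 0.06)])

    def test_signed_weights_optional(self):
        g = build_graph(ringset_from_edges([(1, 2, -0.05)]), use_magnitude=False)
        assert g.graph.edges[1, 2]["weight"] == pytest.approx(-0.05)


class TestFilterGraph:
    def test_weight_floor_is_strict(self):
        g = network_from_edges(
            [(n, n + 1, 0.012) for n in range(1, 6)]
            + [(1, 3, 0.015)]   # exactly at the floor: removed
            + [(i, j, 0.05) for i, j in itertools.combinations(range(10, 14), 2)])
        out = filter_graph(g, weight_min=0.015, kcore_k=1)
        assert all(w > 0.015 for _, _, w in out.graph.edges(data="weight"))
        assert (1, 3) not in out.graph.edges

    def test_triangle_dies_at_k3_clique4_survives(self):
        tri = network_from_edges([(1, 2, 0.1), (2, 3, 0.1), (1, 3, 0.1)])
        assert filter_graph(tri, weight_min=0.0, kcore_k=3).n_nodes == 0
        k4 = network_from_edges([(i, j, 0.1) for i, j in
                                 itertools.combinations(range(1, 5), 2)])
        out = filter_graph(k4, weight_min=0.0, kcore_k=3)
        assert set(out.graph.nodes) == {1, 2, 3, 4} and out.n_edges == 6

    def test_kcore_matches_exhaustive_peeling(self):
        """On many random graphs up to 12 nodes, for every k, the filtered
        node and edge sets equal brute-force iterative peeling."""
        rng = np.random.default_rng(77)
        for trial in range(150):
            n = int(rng.integers(2, 13))
            p = rng.uniform(0.1, 0.8)
            edges = [(i, j, 0.1) for i, j in itertools.combinations(range(1, n + 1), 2)
                     if rng.random() < p]
            if not edges:
                continue
            g = network_from_edges(edges)
            for k in (1, 2, 3, 4):
                ours = filter_graph(g, weight_min=0.0, kcore_k=k)
                nodes, kept_edges = peel_kcore([(i, j) for i, j, _ in edges], k)
                assert set(ours.graph.nodes) == nodes
                assert {frozenset(e) for e in ours.graph.edges} == kept_edges
                if ours.n_nodes:
                    assert min(d for _, d in ours.graph.degree) >= k


class TestCommunities:
    def test_two_disjoint_cliques_are_two_communities(self):
        edges = [(i, j, 0.1) for i, j in itertools.combinations(range(1, 6), 2)]
        edges += [(i, j, 0.1) for i, j in itertools.combinations(range(10, 15), 2)]
        g = network_from_edges(edges)
        part = detect_communities(g, seed=0)
        assert sorted(part.sizes()) == [5, 5]
        comms = part.communities()
        assert {frozenset(c) for c in comms} == {frozenset(range(1, 6)),
                                                 frozenset(range(10, 15))}

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(123)
        blocks = [list(range(b * 100, b * 100 + 15)) for b in range(1, 5)]
        edges = []
        for block in blocks:
            for i, j in itertools.combinations(block, 2):
                if rng.random() < 0.7:
                    edges.append((i, j, 0.1))
        for ba, bb in itertools.combinations(blocks, 2):
            for i in ba:
                for j in bb:
                    if rng.random() < 0.02:
                        edges.append((i, j, 0.1))
        g = network_from_edges(edges)
        part = detect_communities(g, resolution=1.0, seed=1)
        nodes = sorted(part.assignment)
        pred = [part.assignment[n] for n in nodes]
        true = [n // 100 for n in nodes]
        assert adjusted_rand_score(true, pred) > 0.9

    def test_deterministic_given_seed_and_relabelled_by_size(self):
        rng = np.random.default_rng(5)
        pairs = {(min(int(i), int(j)), max(int(i), int(j)))
                 for i, j in rng.integers(1, 40, size=(150, 2)) if i != j}
        edges = [(i, j, 0.1) for i, j in sorted(pairs)]
        g = network_from_edges(edges)
        p1 = detect_communities(g, seed=9)
        p2 = detect_communities(g, seed=9)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity
        sizes = p1.sizes()
        assert sizes == sorted(sizes, reverse=True)
        assert sorted(set(p1.assignment.values())) == list(range(len(sizes)))

    def test_modularity_beats_trivial_partition(self):
        edges = [(i, j, 0.1) for i, j in itertools.combinations(range(1, 6), 2)]
        edges += [(i, j, 0.1) for i, j in itertools.combinations(range(10, 15), 2)]
        edges += [(5, 10, 0.01)]
        g = network_from_edges(edges)
        part = detect_communities(g, seed=0)
        trivial = nx.community.modularity(g.graph, [set(g.graph.nodes)],
                                          weight="weight")
        assert part.modularity >= trivial

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(RingNetwork(graph=nx.Graph()))


class TestNodeStrengths:
    def test_weighted_degree_and_bands(self):
        g = network_from_edges([(1, 2, 0.30), (1, 3, 0.001), (2, 3, 0.05)])
        s = node_strengths(g).set_index("position")
        assert s.loc[1, "weighted_degree"] == pytest.approx(0.301)
        assert s.loc[1, "strength_category"] == "strong"
        assert s.loc[3, "weighted_degree"] == pytest.approx(0.051)
        assert s.loc[3, "strength_category"] == "weak"

    def test_boundaries_medium_inclusive(self):
        g = network_from_edges([(1, 2, 0.25), (3, 4, 0.1), (5, 6, 0.0999)])
        s = node_strengths(g).set_index("position")
        assert s.loc[1, "strength_category"] == "medium"   # 0.25 not strong
        assert s.loc[3, "strength_category"] == "medium"   # 0.1 is medium
        assert s.loc[5, "strength_category"] == "weak"


class TestEdgeCategories:
    def test_nearest_rank_example(self):
        g = network_from_edges([(1, 2, 0.1), (3, 4, 0.2), (5, 6, 0.3), (7, 8, 0.4)])
        cats, thresholds = edge_categories(g)
        by_w = dict(zip(cats["weight"].round(6), cats["strength_category"]))
        assert by_w == {0.1: "weak", 0.2: "weak", 0.3: "medium", 0.4: "strong"}
        assert thresholds == {"p50": pytest.approx(0.3), "p75": pytest.approx(0.4)}

    def test_all_equal_weights_all_strong(self):
        g = network_from_edges([(1, 2, 0.2), (3, 4, 0.2), (5, 6, 0.2), (7, 8, 0.2)])
        cats, _ = edge_categories(g)
        assert (cats["strength_category"] == "strong").all()

    def test_invariant_under_rescaling(self):
        rng = np.random.default_rng(31)
        weights = rng.uniform(0.01, 0.2, size=20)
        edges = [(2 * k + 1, 2 * k + 2, w) for k, w in enumerate(weights)]
        base, _ = edge_categories(network_from_edges(edges))
        scaled, _ = edge_categories(network_from_edges(
            [(i, j, 3.0 * w) for i, j, w in edges]))
        assert list(base["strength_category"]) == list(scaled["strength_category"])

    def test_under_four_edges_unranked(self):
        cats, thresholds = edge_categories(
            network_from_edges([(1, 2, 0.1), (3, 4, 0.2), (5, 6, 0.3)]))
        assert (cats["strength_category"] == "unranked").all()
        assert thresholds == {"p50": None, "p75": None}


class TestCrossCommunity:
    def _bridged_cliques(self):
        edges = [(i, j, 0.1) for i, j in itertools.combinations(range(1, 6), 2)]
        edges += [(i, j, 0.1) for i, j in itertools.combinations(range(10, 15), 2)]
        edges += [(5, 10, 0.07)]
        g = network_from_edges(edges)
        part = detect_communities(g, seed=0)
        return g, part

    def test_single_bridge_recovered_and_symmetric(self):
        g, part = self._bridged_cliques()
        ca, cb = part.assignment[1], part.assignment[10]
        assert ca != cb
        bridge = cross_community_edges(g, part, ca, cb)
        assert bridge == [(5, 10, pytest.approx(0.07))]
        assert cross_community_edges(g, part, cb, ca) == bridge

    def test_same_community_gives_empty(self):
        g, part = self._bridged_cliques()
        ca = part.assignment[1]
        assert cross_community_edges(g, part, ca, ca) == []

    def test_unknown_community_rejected(self):
        g, part = self._bridged_cliques()
        with pytest.raises(ValueError):
            cross_community_edges(g, part, 0, 99)

    def test_planted_interblock_edges_exact(self):
        rng = np.random.default_rng(6)
        blocks = [list(range(b * 50, b * 50 + 8)) for b in range(1, 5)]
        edges = [(i, j, 0.1) for block in blocks
                 for i, j in itertools.combinations(block, 2)]
        planted = [(8 * 6 + 2, 101, 0.05), (55, 152, 0.05), (103, 201, 0.05)]
        g = network_from_edges(edges + planted)
        part = CommunityPartition(
            assignment={n: b for b, block in enumerate(blocks) for n in block},
            modularity=0.0, resolution=1.0)
        found = cross_community_edges(g, part, 0, 2)
        assert found == [(55, 152, pytest.approx(0.05))]


class TestDifferentialEdges:
    def test_identical_networks_no_calls(self):
        g = network_from_edges([(1, 2, 0.05), (3, 4, 0.02)])
        assert differential_edges(g, g) == []

    def test_new_edge_is_strengthened(self):
        a = network_from_edges([(1, 2, 0.05)])
        b = network_from_edges([(1, 2, 0.05), (3, 4, 0.05)])
        (d,) = differential_edges(a, b)
        assert (d.i, d.j) == (3, 4)
        assert d.classification == "strengthened"
        assert d.weight_a == 0.0 and d.weight_b == pytest.approx(0.05)

    def test_swap_exchanges_classes(self):
        a = network_from_edges([(1, 2, 0.05), (3, 4, 0.10)])
        b = network_from_edges([(1, 2, 0.09), (3, 4, 0.02)])
        fwd = {(d.i, d.j): d.classification for d in differential_edges(a, b)}
        rev = {(d.i, d.j): d.classification for d in differential_edges(b, a)}
        assert fwd == {(1, 2): "strengthened", (3, 4): "weakened"}
        assert rev == {(1, 2): "weakened", (3, 4): "strengthened"}

    def test_small_changes_below_delta_min_ignored(self):
        a = network_from_edges([(1, 2, 0.050)])
        b = network_from_edges([(1, 2, 0.055)])
        assert differential_edges(a, b, delta_min=0.01) == []


class TestExports:
    def test_graphml_and_community_tsv(self, tmp_path):
        edges = [(i, j, 0.1) for i, j in itertools.combinations(range(1, 6), 2)]
        g = filter_graph(network_from_edges(edges), weight_min=0.0, kcore_k=3)
        part = detect_communities(g, seed=0)
        gml = tmp_path / "net.graphml"
        write_graphml(gml, g, part)
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == 5
        node = back.nodes[list(back.nodes)[0]]
        assert {"community", "degree", "weighted_degree",
                "strength_category"} <= set(node)
        tsv = tmp_path / "comm.tsv"
        write_community_tsv(tsv, part)
        body = tsv.read_text().splitlines()
        assert body[1] == "position\tcommunity"
        assert len(body) == 2 + 5
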
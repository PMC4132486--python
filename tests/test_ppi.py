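"""PPI loading, seed expansion, geodesic enumeration and three-phase pruning,
checked against exhaustive brute-force enumeration on small graphs."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import topodiff as td
from topodiff.ppi import write_edge_list


# --- brute-force oracle -------------------------------------------------------

def enumerate_geodesics(graph, u, v):
    """Depth-limited simple-path enumeration, keeping only minimum length."""
    paths = [tuple(p) for p in nx.all_simple_paths(graph, u, v,
                                                   cutoff=graph.number_of_nodes())]
    if not paths:
        return set()
    shortest = min(len(p) for p in paths)
    return {p for p in paths if len(p) == shortest}


def brute_force_prune(graph, seeds):
    """Phase-by-phase literal re-enactment of the pruning procedure."""
    seeds = set(seeds) & set(graph.nodes())
    pair_paths = {}
    for u, v in combinations(sorted(seeds), 2):
        paths = enumerate_geodesics(graph, u, v)
        if paths:
            pair_paths[(u, v)] = paths
    # phase 2
    survivors = {}
    for pair, paths in pair_paths.items():
        m = max(sum(1 for x in p if x in seeds) for p in paths)
        survivors[pair] = {p for p in paths
                           if sum(1 for x in p if x in seeds) == m}
    # phase 3
    n_i = {}
    for paths in survivors.values():
        for p in paths:
            for x in p:
                if x not in seeds:
                    n_i[x] = n_i.get(x, 0) + 1
    retained = set()
    for pair, paths in survivors.items():
        scores = {p: sum(n_i.get(x, 0) for x in p if x not in seeds)
                  for p in paths}
        top = max(scores.values())
        for p, s in scores.items():
            if s == top:
                retained.update(x for x in p if x not in seeds)
    return seeds | retained


# --- I/O ---------------------------------------------------------------------

class TestReadEdgeList:
    def test_reverse_duplicates_collapse(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\n")
        g = td.read_edge_list(path)
        assert g.number_of_edges() == 1

    def test_self_loops_dropped(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tA\nA\tB\n")
        g = td.read_edge_list(path)
        assert set(g.edges()) == {("A", "B")}
        assert "self-loop" in caplog.text

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("")
        g = td.read_edge_list(path)
        assert g.number_of_nodes() == 0
        assert "empty" in caplog.text

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nlonely\n")
        with pytest.raises(ValueError, match=":2"):
            td.read_edge_list(path)

    def test_roundtrip(self, tmp_path):
        g, _ = td.simulate_ppi(20, 0.2, 3, seed=0)
        write_edge_list(g, tmp_path / "out.tsv")
        back = td.read_edge_list(tmp_path / "out.tsv")
        assert set(map(frozenset, back.edges())) == set(map(frozenset, g.edges()))


# --- seed expansion ----------------------------------------------------------

class TestSeedExpansion:
    def test_single_component_returned_exactly(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        sub = td.seed_expansion(g, {"a"})
        assert set(sub.nodes()) == {"a", "b", "c"}

    def test_isolated_seed_kept(self):
        g = nx.Graph()
        g.add_node("s")
        g.add_edge("x", "y")
        sub = td.seed_expansion(g, {"s"})
        assert set(sub.nodes()) == {"s"}

    def test_two_of_three_components(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        sub = td.seed_expansion(g, {"a", "e"})
        # oracle: brute-force component labeling
        expected = set()
        for comp in nx.connected_components(g):
            if comp & {"a", "e"}:
                expected |= comp
        assert set(sub.nodes()) == expected == {"a", "b", "e", "f"}

    def test_no_seed_present_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            td.seed_expansion(g, {"zz"})


# --- shortest paths ----------------------------------------------------------

class TestAllShortestPaths:
    def test_adjacent_pair_single_path(self):
        g = nx.Graph([("u", "v"), ("v", "w")])
        assert td.all_shortest_paths(g, "u", "v") == {("u", "v")}

    def test_four_cycle_has_two_geodesics(self):
        g = nx.cycle_graph(["a", "b", "c", "d"])
        assert td.all_shortest_paths(g, "a", "c") == {("a", "b", "c"),
                                                      ("a", "d", "c")}

    def test_disconnected_pair_empty(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        assert td.all_shortest_paths(g, "a", "x") == set()

    def test_unknown_node_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(KeyError):
            td.all_shortest_paths(g, "a", "zz")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        g, _ = td.simulate_ppi(12, 0.25, 2, seed=seed)
        nodes = sorted(g.nodes())
        rng = np.random.default_rng(seed)
        u, v = rng.choice(nodes, 2, replace=False)
        assert td.all_shortest_paths(g, u, v) == enumerate_geodesics(g, u, v)


# --- pruning -----------------------------------------------------------------

class TestPrune:
    def test_adjacent_seeds_need_no_nonseeds(self):
        g = nx.Graph([("s1", "s2")])
        pruned = td.prune(g, {"s1", "s2"})
        assert pruned.retained_nodes == {"s1", "s2"}

    def test_seed_rich_geodesic_displaces_nonseed_path(self):
        # s1-u-s2 vs s1-s3-s2: the all-seed path carries M=3 seeds, u drops
        g = nx.Graph([("s1", "u"), ("u", "s2"), ("s1", "s3"), ("s3", "s2")])
        pruned = td.prune(g, {"s1", "s2", "s3"})
        assert pruned.retained_nodes == {"s1", "s2", "s3"}
        assert pruned.per_pair_M[("s1", "s2")] == 3

    def test_tied_geodesics_both_kept(self):
        # two 2-hop geodesics tie on M and N_p; the 3-edge detour never enters
        g = nx.Graph([("s1", "u"), ("u", "s2"), ("s1", "v"), ("v", "s2"),
                      ("s1", "w"), ("w", "x"), ("x", "s2")])
        pruned = td.prune(g, {"s1", "s2"})
        assert pruned.retained_nodes == {"s1", "s2", "u", "v"}

    def test_phase3_prefers_shared_nonseeds(self):
        # hub h lies on geodesics of both seed pairs; rival r serves only one
        g = nx.Graph([("s1", "h"), ("h", "s2"), ("s1", "r"), ("r", "s2"),
                      ("s3", "h"), ("h", "s2")])
        g.add_edge("s3", "q")
        g.add_edge("q", "s1")
        pruned = td.prune(g, {"s1", "s2", "s3"})
        assert "h" in pruned.retained_nodes
        assert pruned.node_counts["h"] >= pruned.node_counts.get("r", 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_graphs(self, seed):
        g, seeds = td.simulate_ppi(10, 0.3, 3, seed=seed)
        seeds = seeds & set(g.nodes())
        if not seeds:
            pytest.skip("no seeds landed in the graph")
        pruned = td.prune(g, seeds)
        assert pruned.retained_nodes == brute_force_prune(g, seeds)

    @pytest.mark.parametrize("seed", range(200))
    def test_seed_connectivity_always_preserved(self, seed):
        g, seeds = td.simulate_ppi(12, 0.22, 4, seed=1000 + seed)
        pruned = td.prune(g, seeds)
        out = pruned.to_graph()
        for u, v in combinations(sorted(seeds), 2):
            if nx.has_path(g, u, v):
                assert nx.has_path(out, u, v)

    @pytest.mark.parametrize("seed", range(10))
    def test_repruning_only_shrinks_and_stays_connected(self, seed):
        # re-pruning the output can drop further tie-coupled nonseeds (the
        # surviving geodesic set changed) but never adds nodes or breaks
        # seed connectivity
        g, seeds = td.simulate_ppi(12, 0.3, 4, seed=seed)
        pruned = td.prune(g, seeds)
        assert pruned.retained_nodes <= set(g.nodes())
        again = td.prune(pruned.to_graph(), seeds)
        assert again.retained_nodes <= pruned.retained_nodes
        out = again.to_graph()
        for u, v in combinations(sorted(seeds), 2):
            if nx.has_path(g, u, v):
                assert nx.has_path(out, u, v)


# --- connectivity split & modules --------------------------------------------

def _nets_with_degrees(degrees1, degrees2):
    """Star-based networks giving each listed gene a prescribed degree."""
    def build(degrees):
        genes = list(degrees) + [f"aux{i}" for i in range(max(degrees.values()) + 1)]
        adj = np.zeros((len(genes), len(genes)), dtype=np.uint8)
        idx = {g: i for i, g in enumerate(genes)}
        for gene, d in degrees.items():
            for k in range(d):
                adj[idx[gene], idx[f"aux{k}"]] = 1
                adj[idx[f"aux{k}"], idx[gene]] = 1
        return td.CoexprNetwork(genes, adj)
    return build(degrees1), build(degrees2)


class TestSplitByConnectivity:
    def test_split_and_ties(self):
        n1, n2 = _nets_with_degrees({"a": 5, "b": 1, "c": 3},
                                    {"a": 2, "b": 4, "c": 3})
        side1, side2, ties = td.split_by_connectivity({"a", "b", "c"}, n1, n2)
        assert side1 == {"a"}
        assert side2 == {"b"}
        assert ties == {"c"}

    def test_tie_accounting_adds_to_both_cores(self):
        # 113 genes split 63/45 with 5 ties -> module cores of 68 and 50
        degrees1 = {f"g{i}": (5 if i < 63 else 1 if i < 108 else 3)
                    for i in range(113)}
        degrees2 = {f"g{i}": (1 if i < 63 else 5 if i < 108 else 3)
                    for i in range(113)}
        n1, n2 = _nets_with_degrees(degrees1, degrees2)
        side1, side2, ties = td.split_by_connectivity(set(degrees1), n1, n2)
        assert (len(side1), len(side2), len(ties)) == (63, 45, 5)
        assert len(side1 | ties) == 68
        assert len(side2 | ties) == 50


class TestBuildModules:
    def test_disjoint_cores_unchanged(self):
        ppi = nx.Graph([("a", "x"), ("b", "y")])
        m1, m2 = td.build_modules({"a"}, {"b"}, set(), ppi)
        assert m1.members == {"a", "x"}
        assert m2.members == {"b", "y"}

    def test_shared_neighbor_removed_from_both(self):
        ppi = nx.Graph([("a", "x"), ("b", "x")])
        m1, m2 = td.build_modules({"a"}, {"b"}, set(), ppi)
        assert "x" not in m1.members and "x" not in m2.members
        assert m1.members == {"a"} and m2.members == {"b"}

    def test_ten_node_toy_matches_hand_enumeration(self):
        edges = [("c1", "n1"), ("c2", "n1"), ("c3", "n2"), ("d1", "n3"),
                 ("d2", "n3"), ("d1", "n1"), ("c1", "c2"), ("n2", "n4"),
                 ("d2", "n5"), ("n5", "c3")]
        ppi = nx.Graph(edges)
        m1, m2 = td.build_modules({"c1", "c2", "c3"}, {"d1", "d2"}, set(), ppi)
        # by hand: nbrs(core1) = {n1, n2, n5}; nbrs(core2) = {n1, n3, n5}
        # shared n1, n5 removed from both members
        assert m1.members == {"c1", "c2", "c3", "n2"}
        assert m2.members == {"d1", "d2", "n3"}
        assert m1.members.isdisjoint(m2.members)

    def test_unmapped_ids_dropped_and_empty_rejected(self, caplog):
        ppi = nx.Graph([("a", "x")])
        m1, m2 = td.build_modules({"a", "zz"}, set(), set(), ppi)
        assert m1.members == {"a", "x"}
        with pytest.raises(ValueError):
            td.build_modules({"qq"}, {"zz"}, set(), ppi)
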
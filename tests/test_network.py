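"""Minimum-spanning and median-joining networks, MP trees, back mutations."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

from mtcr.haplotypes import HVR1_NETWORK, HaploPanel, Haplotype
from mtcr.network import (
    MJParams,
    build_mj,
    build_msn,
    count_back_mutations,
    find_nodes_by_motif,
    mp_extract,
)
from mtcr.haplotypes import trim_to_regions
from mtcr.simulate import SimConfig, simulate_panel
from mtcr.sites import WeightScheme, builtin_exclusions

from conftest import hap_from_bits, make_tree, panel_from_bits


def edge_sets(graph):
    return set(map(frozenset, graph.edges))


class TestMSN:
    def test_three_states_star_from_ancestor(self):
        net = build_msn(panel_from_bits({"AA": "00", "AG": "01", "GA": "10"}))
        assert edge_sets(net.graph) == {
            frozenset({"AA", "AG"}),
            frozenset({"AA", "GA"}),
        }

    def test_four_states_give_a_cycle(self):
        net = build_msn(
            panel_from_bits({"AA": "00", "AG": "01", "GA": "10", "GG": "11"})
        )
        assert edge_sets(net.graph) == {
            frozenset({"AA", "AG"}),
            frozenset({"AA", "GA"}),
            frozenset({"AG", "GG"}),
            frozenset({"GA", "GG"}),
        }

    def test_msn_exact_by_brute_force_on_random_panels(self):
        # oracle: an edge (u,v) is in the MSN iff in the Kruskal-by-distance-
        # class process u and v are still in different components when the
        # class of d(u,v) starts
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            bits = {f"h{i}": "".join(map(str, rng.integers(0, 2, 5)))
                    for i in range(n)}
            # dedupe
            bits = {hid: b for hid, b in bits.items()}
            panel = panel_from_bits(bits)
            net = build_msn(panel)
            ids = net.sampled_ids
            haps = {i: net.node(i).haplotype for i in ids}
            from mtcr.haplotypes import pairwise_distance
            dist = {
                frozenset({a, b}): pairwise_distance(haps[a], haps[b])[0]
                for a, b in itertools.combinations(ids, 2)
            }
            expected = set()
            parent = {i: i for i in ids}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for d in sorted(set(dist.values())):
                klass = [e for e, dd in dist.items() if dd == d]
                comps_before = {i: find(i) for i in ids}
                for e in klass:
                    a, b = tuple(e)
                    if comps_before[a] != comps_before[b]:
                        expected.add(e)
                for e in klass:
                    a, b = tuple(e)
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
            assert edge_sets(net.graph) == expected

    def test_all_identical_panel_collapses_to_single_node(self):
        panel = panel_from_bits({"a": "01", "b": "01", "c": "01"})
        net = build_msn(panel)
        assert net.graph.number_of_nodes() == 1
        assert net.node("a").multiplicity == 3

    def test_weights_can_change_the_msn(self):
        # sites 101,102 vs site 103: with uniform weights h3 ties; with a
        # light weight on 103 the two-step path through 103 wins
        panel = panel_from_bits({"a": "000", "b": "110", "c": "001"})
        uniform = build_msn(panel)
        assert frozenset({"a", "c"}) in edge_sets(uniform.graph)
        scheme = WeightScheme({101: 10, 102: 10, 103: 1})
        weighted = build_msn(panel, MJParams(weights=scheme))
        d_ab = weighted.graph.edges["a", "b"]["weight"] if weighted.graph.has_edge("a", "b") else None
        assert weighted.graph.has_edge("a", "c")
        assert weighted.graph.edges["a", "c"]["weight"] == 1


class TestMJ:
    def test_median_already_sampled_adds_nothing(self):
        panel = panel_from_bits({"AAA": "000", "AAG": "001", "AGG": "011"})
        net = build_mj(panel)
        assert net.median_ids == []
        assert set(net.node_ids) == {"AAA", "AAG", "AGG"}

    def test_steiner_point_added_for_three_way_split(self):
        # {CCC, CTT, TCT}: all pairwise distances 2; the site-wise majority
        # median CCT turns the triangle into a star of unit edges
        panel = panel_from_bits({"x": "000", "y": "011", "z": "101"})
        net = build_mj(panel)
        assert len(net.median_ids) == 1
        mv = net.node(net.median_ids[0])
        assert sorted(v.position for v in mv.haplotype.variants) == [103]
        for sample in ("x", "y", "z"):
            assert net.graph.has_edge(mv.id, sample)
            assert net.graph.edges[mv.id, sample]["weight"] == 1

    def test_epsilon_zero_four_cycle_needs_no_median(self):
        panel = panel_from_bits({"AA": "00", "AG": "01", "GA": "10", "GG": "11"})
        net = build_mj(panel)
        assert net.median_ids == []

    def test_mj_contains_msn_on_random_panels(self):
        rng = np.random.default_rng(17)
        for trial in range(15):
            cfg = SimConfig(
                seed=4000 + trial,
                n_tips=12,
                T_true=700.0,
                region_set=(HVR1_NETWORK,),
                missing_hvr2_fraction=0.0,
            )
            panel, _, _ = simulate_panel(cfg)
            msn, mj = build_msn(panel), build_mj(panel)
            assert set(msn.graph.nodes) <= set(mj.graph.nodes)
            assert edge_sets(msn.graph) <= edge_sets(mj.graph)

    def test_node_order_permutation_changes_ids_only(self):
        bits = {"a": "0000", "b": "0011", "c": "0101", "d": "1001", "e": "1111"}
        panel1 = panel_from_bits(bits)
        panel2 = panel_from_bits(dict(reversed(list(bits.items()))))
        n1, n2 = build_mj(panel1), build_mj(panel2)
        sig1 = sorted(
            tuple(sorted(
                tuple(sorted(v.label for v in n1.node(x).haplotype.variants))
                for x in e
            ))
            for e in n1.graph.edges
        )
        sig2 = sorted(
            tuple(sorted(
                tuple(sorted(v.label for v in n2.node(x).haplotype.variants))
                for x in e
            ))
            for e in n2.graph.edges
        )
        assert sig1 == sig2

    def test_uruguay_hvr1_network_links_ancestral_motif(self, uruguay_panel):
        trimmed = trim_to_regions(uruguay_panel, [HVR1_NETWORK])
        net = build_mj(trimmed, MJParams(excluded=builtin_exclusions("network_hvr1")))
        root = find_nodes_by_motif(
            net.graph, {"16051G", "16223T", "16298C", "16325C", "16327T"}
        )
        assert len(root) == 1
        # the ancestral motif node collapses KC049+KP079 and is connected
        assert net.node(root[0]).multiplicity >= 2
        assert nx.is_connected(net.graph)
        assert net.graph.degree(root[0]) >= 3


class TestMP:
    def test_tree_shaped_network_returns_itself(self):
        panel = panel_from_bits({"AA": "00", "AG": "01", "GA": "10"})
        net = build_msn(panel)
        trees, pruned, n = mp_extract(net)
        assert n == 1
        assert edge_sets(trees[0].graph) == edge_sets(net.graph)

    def test_four_cycle_yields_four_trees(self):
        panel = panel_from_bits({"AA": "00", "AG": "01", "GA": "10", "GG": "11"})
        trees, pruned, n = mp_extract(build_mj(panel))
        assert n == 4
        assert all(t.total_weighted_length == 3 for t in trees)
        assert edge_sets(pruned.graph) == edge_sets(build_msn(panel).graph)

    def test_exact_mode_refuses_above_cap(self):
        panel = panel_from_bits(
            {f"h{i}": format(i, "04b") for i in range(10)}
        )
        net = build_mj(panel)
        with pytest.raises(ValueError, match="heuristic"):
            mp_extract(net, size_cap=5, mode="exact")

    def test_auto_mode_heuristic_warns_and_returns_tree(self):
        panel = panel_from_bits({f"h{i}": format(i, "04b") for i in range(10)})
        net = build_mj(panel)
        with pytest.warns(UserWarning, match="heuristic"):
            trees, pruned, n = mp_extract(net, size_cap=5)
        assert n == 1
        t = trees[0].graph
        assert nx.is_tree(t)
        assert set(net.sampled_ids) <= set(t.nodes)

    def test_branch_and_bound_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            n_hap = int(rng.integers(3, 9))
            n_sites = int(rng.integers(3, 11))
            seen, bits = set(), {}
            while len(bits) < n_hap:
                b = "".join(map(str, rng.integers(0, 2, n_sites)))
                if b not in seen:
                    seen.add(b)
                    bits[f"h{len(bits)}"] = b
            net = build_mj(panel_from_bits(bits))
            trees, _, _ = mp_extract(net, mode="exact")
            assert trees[0].total_weighted_length == pytest.approx(
                _oracle_steiner_minimum(net.graph, set(net.sampled_ids))
            )

    def test_every_mp_tree_no_longer_than_any_sampled_spanning_tree(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            bits = {f"h{i}": "".join(map(str, rng.integers(0, 2, 6)))
                    for i in range(6)}
            net = build_mj(panel_from_bits(bits))
            trees, _, _ = mp_extract(net, mode="exact")
            sampled = set(net.sampled_ids)
            sub = net.graph.subgraph(sampled)
            if sub.number_of_nodes() > 1 and nx.is_connected(sub):
                mst_w = nx.minimum_spanning_tree(sub, weight="weight").size(
                    weight="weight"
                )
                assert trees[0].total_weighted_length <= mst_w + 1e-9


def _oracle_steiner_minimum(graph, sampled):
    """Independent oracle: enumerate every subset of optional nodes and every
    spanning edge combination; return the minimum spanning weight."""
    medians = [n for n in graph.nodes if n not in sampled]
    best = float("inf")
    for r in range(len(medians) + 1):
        for extra in itertools.combinations(medians, r):
            nodes = list(sampled) + list(extra)
            sub = graph.subgraph(nodes)
            m = len(nodes) - 1
            edges = list(sub.edges(data="weight"))
            if len(edges) < m:
                continue
            for combo in itertools.combinations(edges, m):
                t = nx.Graph()
                t.add_nodes_from(nodes)
                t.add_weighted_edges_from(combo)
                if nx.is_connected(t):
                    best = min(best, sum(w for _, _, w in combo))
    return best


class TestBackMutations:
    def test_unique_site_per_edge_means_zero(self):
        tree = make_tree({("root", "a"): 2, ("a", "b"): 3}, {"a": 1, "b": 1})
        assert count_back_mutations(tree) == 0

    def test_spanning_tree_of_four_cycle_has_one(self):
        panel = panel_from_bits({"AA": "00", "AG": "01", "GA": "10", "GG": "11"})
        trees, _, _ = mp_extract(build_mj(panel))
        # every spanning tree of the 4-cycle reuses exactly one site
        assert all(count_back_mutations(t) == 1 for t in trees)

    def test_two_keys_on_three_edges_each_count_four(self):
        g = nx.Graph()
        from mtcr.network import MPTree, NetNode

        placeholder = Haplotype("x", frozenset())
        for i in range(4):
            g.add_node(f"n{i}", node=NetNode(f"n{i}", placeholder, True, 1))
        keys = (("sub", 1), ("sub", 2))
        for i in range(3):
            g.add_edge(f"n{i}", f"n{i+1}", weight=2, keys=keys)
        tree = MPTree(g, 6.0)
        assert count_back_mutations(tree) == 4

    def test_hotspot_exclusion_never_increases_back_mutations(self):
        # recurrence concentrates at hotspot sites, so removing them from the
        # comparison cannot make the minimal explanation worse
        excl = builtin_exclusions("network_hvr1")
        for seed in range(10):
            cfg = SimConfig(
                seed=6000 + seed,
                n_tips=10,
                T_true=900.0,
                region_set=(HVR1_NETWORK,),
                missing_hvr2_fraction=0.0,
            )
            panel, _, _ = simulate_panel(cfg)
            counts = {}
            for tag, e in (("raw", None), ("excl", excl)):
                net = build_mj(panel, MJParams(excluded=e))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    trees, _, _ = mp_extract(net)
                counts[tag] = min(count_back_mutations(t) for t in trees)
            assert counts["excl"] <= counts["raw"]
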
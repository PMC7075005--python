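"""Knockout-perturbation engine: efficacies, network efficiency, NED ranking."""

import math
from fractions import Fraction

import networkx as nx
import pytest

from herbnet import (
    BipartiteMap,
    edge_efficacy,
    knockout,
    network_efficiency,
    pathway_efficacy,
    project,
    rank_all,
    shortest_path_matrix,
    top_fraction,
)
from herbnet.data_model import display_percent
from herbnet.synthetic import SyntheticSpec, random_bipartite

# Frozen worked-example values (exact arithmetic checked below):
NE0_EXACT = 83 / 6  # 13.8333...
NE_KNOCK_C = 8.476143790849672  # Dijkstra over the knock-C length matrix
KNOCK_C_LENGTHS = {
    ("A", "B"): 1.5, ("A", "C"): 1.5, ("B", "C"): 2.25, ("B", "E"): 1.5,
    ("C", "D"): 2.0, ("C", "E"): 1.5, ("C", "F"): 2.0, ("F", "G"): 1.0,
}


def floyd_warshall_efficiency(graph, lengths=None):
    """Independent oracle: triple-loop Floyd-Warshall, then sum of 1/d."""
    nodes = sorted(graph.nodes())
    d = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        d[u][u] = 0.0
    for u, v in graph.edges():
        w = 1.0
        if lengths is not None:
            w = float(lengths.get((u, v), lengths.get((v, u), 1)))
        d[u][v] = d[v][u] = min(d[u][v], w)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return sum(
        1.0 / d[u][v]
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if math.isfinite(d[u][v]) and d[u][v] > 0
    )


class TestPathwayEfficacy:
    @pytest.mark.parametrize(
        "size, member, expected, percent",
        [
            (3, True, Fraction(2, 3), 67),
            (2, True, Fraction(1, 2), 50),
            (3, False, Fraction(1), 100),
            (10, False, Fraction(1), 100),
        ],
    )
    def test_exact_fraction_and_display(self, size, member, expected, percent):
        pe = pathway_efficacy(size, member)
        assert pe == expected
        assert display_percent(pe) == percent

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            pathway_efficacy(0, True)


class TestEdgeEfficacy:
    def test_two_affected_size3_pathways(self):
        ee, length = edge_efficacy([3, 3], [True, True])
        assert ee == Fraction(4, 9)
        assert length == Fraction(9, 4)
        assert float(length) == 2.25

    def test_single_affected_size2_pathway(self):
        ee, length = edge_efficacy([2], [True])
        assert (ee, length) == (Fraction(1, 2), Fraction(2))

    def test_unaffected_edge_keeps_unit_length(self):
        ee, length = edge_efficacy([2], [False])
        assert (ee, length) == (1, 1)

    def test_length_times_efficacy_is_exactly_one(self):
        for n in range(2, 30):
            ee, length = edge_efficacy([n], [True])
            assert length * Fraction(n - 1, n) == 1

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError):
            edge_efficacy([3, 2], [True])


class TestNetworkEfficiency:
    def test_baseline_on_fixture(self, fixture_graph):
        assert network_efficiency(fixture_graph) == pytest.approx(NE0_EXACT, abs=1e-12)

    def test_two_nodes_one_long_edge(self):
        g = nx.Graph([("X", "Y")])
        assert network_efficiency(g, {("X", "Y"): Fraction(2)}) == pytest.approx(0.5)

    def test_knock_c_lengths_reproduce_printed_value(self, fixture_graph):
        ne = network_efficiency(fixture_graph, KNOCK_C_LENGTHS)
        assert ne == pytest.approx(NE_KNOCK_C, abs=1e-9)
        assert ne == pytest.approx(
            floyd_warshall_efficiency(fixture_graph, KNOCK_C_LENGTHS), abs=1e-12
        )

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        assert network_efficiency(g) == pytest.approx(2.0)

    def test_empty_and_singleton_graphs(self):
        assert network_efficiency(nx.Graph()) == 0.0
        g = nx.Graph()
        g.add_node("A")
        assert network_efficiency(g) == 0.0


class TestKnockout:
    def test_knock_c_worked_example(self, fixture_graph, fixture_map):
        res = knockout(fixture_graph, fixture_map, "C")
        assert res.pathway_efficacies == {
            "a": Fraction(2, 3), "b": Fraction(2, 3), "c": 1,
            "d": Fraction(1, 2), "e": Fraction(1, 2), "f": 1,
        }
        for (u, v), expected in KNOCK_C_LENGTHS.items():
            state = res.edge_states.get((u, v)) or res.edge_states[(v, u)]
            assert float(state.length) == expected
        # edge B-C carries both affected size-3 pathways: t=2, EE=4/9
        bc = res.edge_states.get(("B", "C")) or res.edge_states[("C", "B")]
        assert (bc.n_affected, bc.efficacy) == (2, Fraction(4, 9))
        assert res.ne_baseline == pytest.approx(NE0_EXACT, abs=1e-12)
        assert res.ne_perturbed == pytest.approx(NE_KNOCK_C, abs=1e-6)
        assert res.ned == pytest.approx(NE0_EXACT - NE_KNOCK_C, abs=1e-6)

    def test_knock_g_hand_computed_ned(self, fixture_graph, fixture_map):
        # only pathway f={F,G} is affected, so only edge FG stretches to 2;
        # by hand: baseline G-pair reciprocals (1 + 1/2 + 4/3) minus
        # perturbed (1/2 + 1/3 + 1) = 1.
        res = knockout(fixture_graph, fixture_map, "G")
        assert res.ned == pytest.approx(1.0, abs=1e-9)

    def test_pathway_free_target_has_zero_ned(self):
        pairs = [("X", "p"), ("Y", "p"), ("H", "solo")]  # "solo" has one member
        bmap = BipartiteMap(pairs)
        g = project(bmap)
        res = knockout(g, bmap, "H")
        assert res.ned == 0.0

    def test_unknown_target_rejected(self, fixture_graph, fixture_map):
        with pytest.raises(KeyError):
            knockout(fixture_graph, fixture_map, "ZZZ")

    def test_knocked_node_is_retained(self, fixture_graph, fixture_map):
        res = knockout(fixture_graph, fixture_map, "C")
        # C's own pairs still contribute: C-E at 1.5, C-D at 2 etc.
        dist = shortest_path_matrix(fixture_graph,
                                    {e: s.length for e, s in res.edge_states.items()})
        assert dist.loc["C", "E"] == pytest.approx(1.5)
        assert dist.loc["C", "G"] == pytest.approx(3.0)


class TestRanking:
    def test_fixture_ranking_puts_c_first(self, fixture_graph, fixture_map):
        ranked = rank_all(fixture_graph, fixture_map)
        assert ranked[0].knocked_target == "C"
        assert [r.knocked_target for r in ranked] == list("CBFEADG")
        neds = [r.ned for r in ranked]
        assert neds == sorted(neds, reverse=True)

    def test_single_clique_symmetry_breaks_ties_alphabetically(self):
        bmap = BipartiteMap([(t, "p") for t in "DBCA"])
        ranked = rank_all(project(bmap), bmap)
        assert [r.knocked_target for r in ranked] == ["A", "B", "C", "D"]
        assert len({round(r.ned, 12) for r in ranked}) == 1

    def test_ordering_matches_independent_recomputation(self):
        bmap = random_bipartite(
            SyntheticSpec(n_targets=20, n_pathways=6, membership_prob=0.25, seed=3)
        )
        g = project(bmap)
        ranked = rank_all(g, bmap)
        # independent route: networkx Dijkstra for each knockout
        def nx_efficiency(lengths):
            h = nx.Graph()
            h.add_nodes_from(g.nodes())
            for (u, v), w in lengths.items():
                h.add_edge(u, v, weight=float(w))
            total = 0.0
            for u, dists in dict(nx.all_pairs_dijkstra_path_length(h, weight="weight")).items():
                for v, d in dists.items():
                    if u < v and d > 0:
                        total += 1.0 / d
            return total

        ne0 = nx_efficiency({e: 1 for e in g.edges()})
        expected = []
        for t in sorted(g.nodes()):
            lengths = {}
            for u, v, data in g.edges(data=True):
                length = Fraction(1)
                for p in data["pathways"]:
                    if t in bmap.members(p):
                        n = bmap.pathway_size(p)
                        length *= Fraction(n, n - 1)
                lengths[(u, v)] = length
            expected.append((t, ne0 - nx_efficiency(lengths)))
        expected.sort(key=lambda item: (-item[1], item[0]))
        assert [r.knocked_target for r in ranked] == [t for t, _ in expected]
        for r, (_, ned) in zip(ranked, expected):
            assert r.ned == pytest.approx(ned, abs=1e-9)

    def test_label_permutation_permutes_ned_values(self, fixture_map):
        mapping = dict(zip("ABCDEFG", "TUVWXYZ"))
        relabeled = BipartiteMap(
            [(mapping[t], p) for t, p in fixture_map.pairs]
        )
        orig = {r.knocked_target: r.ned for r in rank_all(project(fixture_map), fixture_map)}
        new = {r.knocked_target: r.ned for r in rank_all(project(relabeled), relabeled)}
        for t, ned in orig.items():
            assert new[mapping[t]] == pytest.approx(ned, abs=1e-12)


class TestNedProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_ned_nonnegative_on_random_maps(self, seed):
        bmap = random_bipartite(
            SyntheticSpec(
                n_targets=15, n_pathways=5, membership_prob=0.3, seed=100 + seed
            )
        )
        g = project(bmap)
        assert all(r.ned >= -1e-12 for r in rank_all(g, bmap))

    @pytest.mark.parametrize("seed", range(5))
    def test_efficiency_matches_floyd_warshall_oracle(self, seed):
        bmap = random_bipartite(
            SyntheticSpec(
                n_targets=10, n_pathways=4, membership_prob=0.35,
                seed=200 + seed, on_small="drop",
            )
        )
        g = project(bmap)
        assert network_efficiency(g) == pytest.approx(
            floyd_warshall_efficiency(g), abs=1e-9
        )


class TestTopFraction:
    def test_paper_scale_rule(self):
        ranked = list(range(279))  # only the length matters
        assert len(top_fraction(ranked, 0.10)) == 28

    @pytest.mark.parametrize(
        "n, fraction, expected", [(10, 0.10, 1), (7, 1.0, 7), (28, 0.10, 3), (1, 0.5, 1)]
    )
    def test_ceiling_rule(self, n, fraction, expected):
        assert len(top_fraction(list(range(n)), fraction)) == expected

    def test_empty_and_invalid(self):
        assert top_fraction([], 0.1) == []
        with pytest.raises(ValueError):
            top_fraction([1], 0.0)
        with pytest.raises(ValueError):
            top_fraction([1], 1.5)

    def test_selects_a_prefix(self, fixture_graph, fixture_map):
        ranked = rank_all(fixture_graph, fixture_map)
        assert top_fraction(ranked, 0.3) == ranked[:3]
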
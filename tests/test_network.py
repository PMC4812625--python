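import itertools

import networkx as nx
import pytest

from molsimnet.network import (
    NoPeakError,
    SimilarityNetwork,
    ThresholdScan,
    apply_threshold,
    average_clustering_coefficient,
    clustering_coefficient,
    edge_count,
    find_t_alpha,
    scan,
    threshold_grid,
)
from molsimnet.similarity import SparseSimilarityMatrix
from molsimnet.synthetic import generate_block_matrix, generate_random_network


def net_from_edges(n, edges, t=0.0):
    nodes = tuple(f"n{i}" for i in range(n))
    return SimilarityNetwork(
        nodes=nodes,
        edges=frozenset((nodes[min(a, b)], nodes[max(a, b)]) for a, b in edges),
        threshold=t,
    )


def complete_net(n):
    return net_from_edges(n, itertools.combinations(range(n), 2))


def brute_force_acc(net):
    """Independent oracle: per-node neighbor-pair enumeration."""
    adj = {v: set() for v in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    ccs = []
    for v in net.nodes:
        nb = sorted(adj[v])
        if len(nb) < 2:
            if nb:
                ccs.append(0.0)
            continue
        links = sum(
            1 for x, y in itertools.combinations(nb, 2) if y in adj[x]
        )
        ccs.append(2 * links / (len(nb) * (len(nb) - 1)))
    return sum(ccs) / len(ccs) if ccs else 0.0


class TestApplyThreshold:
    def small_matrix(self):
        ids = ("A", "B", "C", "D")
        entries = {
            ("A", "B"): 0.9,
            ("A", "C"): 0.7,
            ("B", "C"): 0.69,
            ("A", "D"): 0.2,
            ("B", "D"): 0.1,
            ("C", "D"): 0.15,
        }
        return SparseSimilarityMatrix(ids, entries, t_store=0.0)

    def test_boundary_is_inclusive(self):
        net = apply_threshold(self.small_matrix(), 0.7)
        assert ("A", "C") in net.edges      # s = 0.70 >= t
        assert ("B", "C") not in net.edges  # s = 0.69 < t

    def test_singleton_retained_as_node(self):
        net = apply_threshold(self.small_matrix(), 0.7)
        assert "D" in net.nodes
        assert net.degree("D") == 0
        assert net.singletons() == ["D"]

    def test_below_floor_rejected(self):
        matrix = self.small_matrix().restricted(0.3)
        with pytest.raises(ValueError, match="floor"):
            apply_threshold(matrix, 0.2)

    def test_edge_counts(self):
        matrix = self.small_matrix()
        assert edge_count(apply_threshold(matrix, 0.0)) == 6
        assert edge_count(apply_threshold(matrix, 0.5)) == 3
        assert edge_count(apply_threshold(matrix, 0.95)) == 0


class TestClusteringCoefficient:
    def test_degree_one_is_zero(self):
        net = net_from_edges(3, [(0, 1)])
        assert clustering_coefficient(net, "n0") == 0.0

    def test_isolated_node_is_zero(self):
        net = net_from_edges(2, [])
        assert clustering_coefficient(net, "n0") == 0.0

    def test_triangle_node_is_one(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert all(clustering_coefficient(net, v) == 1.0 for v in net.nodes)

    def test_star_center_is_zero(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficient(net, "n0") == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            clustering_coefficient(net_from_edges(2, []), "zz")


class TestAverageClusteringCoefficient:
    @pytest.mark.parametrize("n", [3, 5, 12])
    def test_complete_network_is_one(self, n):
        assert average_clustering_coefficient(complete_net(n)) == 1.0

    def test_two_node_complete_graph_is_zero_by_definition(self):
        # both nodes have degree 1, so CC = 0 for each by the low-degree rule
        assert average_clustering_coefficient(complete_net(2)) == 0.0

    def test_all_singletons_is_zero(self):
        assert average_clustering_coefficient(net_from_edges(6, [])) == 0.0

    def test_path_is_zero(self):
        assert average_clustering_coefficient(net_from_edges(3, [(0, 1), (1, 2)])) == 0.0

    def test_tree_is_zero(self):
        tree = nx.random_labeled_tree(15, seed=4)
        assert average_clustering_coefficient(net_from_edges(15, tree.edges())) == 0.0

    def test_singletons_excluded_not_averaged_in(self):
        # triangle plus two isolated nodes: ACC stays 1
        net = net_from_edges(5, [(0, 1), (1, 2), (0, 2)])
        assert average_clustering_coefficient(net) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        net = generate_random_network(40, 0.15, seed=seed)
        assert average_clustering_coefficient(net) == pytest.approx(
            brute_force_acc(net), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx_on_random_graphs(self, seed):
        """Cross-check against an independent library implementation."""
        net = generate_random_network(35, 0.2, seed=seed)
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        connected = [v for v in g if g.degree(v) > 0]
        expected = (
            sum(nx.clustering(g, connected).values()) / len(connected)
            if connected
            else 0.0
        )
        assert average_clustering_coefficient(net) == pytest.approx(expected, abs=1e-12)


class TestScan:
    def test_grid_arithmetic(self):
        assert len(threshold_grid(0.30, 1.0, 0.01)) == 71
        assert threshold_grid(0.0, 1.0, 0.3) == [0.0, 0.3, 0.6, 0.9, 1.0]

    def test_identical_molecules_flat_scan(self):
        ids = tuple(f"m{i}" for i in range(5))
        entries = {p: 1.0 for p in itertools.combinations(ids, 2)}
        matrix = SparseSimilarityMatrix(ids, entries, t_store=0.0)
        result = scan(matrix)
        assert all(a == 1.0 for a in result.acc)
        assert all(e == 10 for e in result.en)

    def test_matches_independent_rebuild(self):
        matrix = generate_block_matrix([7, 6, 7], seed=11)
        result = scan(matrix, 0.0, 1.0, 0.05)
        for t, acc_t, en_t, sing_t in zip(
            result.grid, result.acc, result.en, result.singletons
        ):
            net = apply_threshold(matrix, t)
            assert acc_t == pytest.approx(average_clustering_coefficient(net), abs=1e-12)
            assert en_t == edge_count(net)
            assert sing_t == len(net.singletons())

    def test_edge_nesting_and_en_monotone(self):
        matrix = generate_block_matrix([8, 8, 8], seed=5)
        result = scan(matrix)
        assert all(a >= b for a, b in zip(result.en, result.en[1:]))
        prev = apply_threshold(matrix, result.grid[0]).edges
        for t in result.grid[1:]:
            cur = apply_threshold(matrix, t).edges
            assert cur <= prev
            prev = cur

    def test_thresholds_straddling_no_similarity_give_identical_networks(self):
        # engineered gap: no realized similarity in (0.2, 0.7)
        matrix = generate_block_matrix(
            [4, 4], s_intra_range=(0.7, 0.9), s_inter_range=(0.1, 0.2), seed=1
        )
        nets = [apply_threshold(matrix, t) for t in (0.25, 0.3, 0.45, 0.7)]
        assert nets[0].edges == nets[1].edges == nets[2].edges == nets[3].edges

    def test_t_min_below_floor_rejected(self):
        matrix = generate_block_matrix([4, 4], seed=1).restricted(0.5)
        with pytest.raises(ValueError):
            scan(matrix, 0.0, 1.0, 0.01)


def mk_scan(acc):
    grid = [round(0.01 * i, 2) for i in range(len(acc))]
    en = list(range(len(acc), 0, -1))
    return ThresholdScan(grid=grid, acc=acc, en=en, singletons=[0] * len(acc))


class TestFindTAlpha:
    def test_single_interior_peak(self):
        acc = [1.0, 1.0, 0.5, 0.2, 0.4, 0.8, 0.4, 0.2, 0.1, 0.0]
        peak = find_t_alpha(mk_scan(acc))
        assert peak.t_alpha == 0.05
        assert peak.acc_at_alpha == 0.8
        assert peak.peak_lo <= peak.t_alpha <= peak.peak_hi

    def test_leading_plateau_not_selected(self):
        acc = [1.0] * 5 + [0.6, 0.3, 0.7, 0.3, 0.1, 0.0]
        peak = find_t_alpha(mk_scan(acc))
        assert peak.t_alpha == 0.07
        assert peak.acc_at_alpha == 0.7

    def test_widest_span_beats_taller_peak(self):
        # wide low peak (span 10 steps) vs narrow tall peak (span 4 steps)
        acc = (
            [1.0, 0.5, 0.1]
            + [0.2, 0.35, 0.5, 0.55, 0.5, 0.35, 0.25, 0.15, 0.1]  # wide, max 0.55
            + [0.5, 0.9, 0.5, 0.05]                               # narrow, max 0.9
        )
        peak = find_t_alpha(mk_scan(acc))
        assert peak.acc_at_alpha == 0.55
        assert peak.t_alpha == 0.06

    def test_minor_bumps_merge_into_enclosing_peak(self):
        # shallow wiggles (prominence < epsilon) on one broad peak
        acc = [1.0, 0.6, 0.2, 0.5, 0.8, 0.795, 0.8, 0.6, 0.3, 0.1, 0.0]
        peak = find_t_alpha(mk_scan(acc), epsilon=0.01)
        assert peak.t_alpha == 0.04
        assert peak.peak_lo <= 0.03 and peak.peak_hi >= 0.07

    def test_flat_peak_takes_smallest_t(self):
        acc = [1.0, 0.5, 0.2, 0.7, 0.7, 0.7, 0.2, 0.1]
        peak = find_t_alpha(mk_scan(acc))
        assert peak.t_alpha == 0.03

    def test_monotone_decline_has_no_peak(self):
        with pytest.raises(NoPeakError):
            find_t_alpha(mk_scan([1.0, 0.8, 0.6, 0.4, 0.2, 0.0]))

    def test_constant_acc_has_no_peak(self):
        with pytest.raises(NoPeakError):
            find_t_alpha(mk_scan([1.0] * 10))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            find_t_alpha(mk_scan([1.0, 0.5]))


class TestEdgeEditNonMonotonicity:
    def test_exhaustive_small_graphs_show_acc_decrease_on_addition(self):
        """Adding an edge can strictly lower ACC; removing one can raise it.

        Exhaustive search over all graphs on 5 nodes and all candidate
        edges; the same instance witnesses both directions.
        """
        nodes = range(5)
        all_pairs = list(itertools.combinations(nodes, 2))
        witness = None
        for mask in range(2 ** len(all_pairs)):
            edges = [p for k, p in enumerate(all_pairs) if mask >> k & 1]
            base = brute_force_acc(net_from_edges(5, edges))
            for p in all_pairs:
                if p in edges:
                    continue
                grown = brute_force_acc(net_from_edges(5, edges + [p]))
                if grown < base:
                    witness = (edges, p, base, grown)
                    break
            if witness:
                break
        assert witness is not None
        edges, extra, base, grown = witness
        # removal of the same edge from the grown graph increases ACC back
        assert brute_force_acc(net_from_edges(5, edges + [extra])) < base
        assert average_clustering_coefficient(net_from_edges(5, edges + [extra])) < (
            average_clustering_coefficient(net_from_edges(5, edges))
        )
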
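"""Modularity indices, community detection and heatmap bundles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from domarchnet.modularity import (
    Partition,
    age_partition,
    clustering_coefficient,
    fgc,
    heatmap_bundle,
    modularity_report,
    ng_modularity,
    vos_cluster,
    vq_index,
)


def two_triangles(bridge=False):
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    if bridge:
        g.add_edge(2, 3)
    return g


def component_partition(g):
    return Partition({
        n: i for i, comp in enumerate(nx.connected_components(g), 1)
        for n in comp
    })


def brute_force_ng(g, part):
    """Direct double-loop evaluation of Q = 1/2m Σ_ij (A_ij - k_i k_j/2m) δ."""
    nodes = list(g.nodes)
    m = g.size(weight="weight")
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if part.assignment[u] == part.assignment[v]:
                q += a[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


class TestClusteringCoefficient:
    def test_triangle(self):
        assert clustering_coefficient(nx.complete_graph(3)) == 1.0

    def test_path(self):
        assert clustering_coefficient(nx.path_graph(3)) == 0.0

    def test_k4_minus_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        assert clustering_coefficient(g) == pytest.approx(5 / 6)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            clustering_coefficient(nx.Graph())


class TestNgModularity:
    def test_two_disjoint_triangles(self):
        g = two_triangles()
        assert ng_modularity(g, component_partition(g)) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        g = nx.gnm_random_graph(8, 14, seed=1)
        q = ng_modularity(g, Partition({n: 1 for n in g.nodes}))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_singleton_partition_of_k3(self):
        g = nx.complete_graph(3)
        q = ng_modularity(g, Partition({n: n + 1 for n in g.nodes}))
        assert q == pytest.approx(-1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(12, 25, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = int(rng.integers(1, 5))
        part = Partition({n: int(rng.integers(1, 4)) for n in g.nodes})
        assert ng_modularity(g, part) == pytest.approx(brute_force_ng(g, part))


class TestVq:
    def test_two_disjoint_triangles(self):
        g = two_triangles()
        assert vq_index(g, component_partition(g)) == pytest.approx(-0.25)

    def test_single_community_empty_sum(self):
        g = nx.complete_graph(4)
        assert vq_index(g, Partition({n: 1 for n in g.nodes})) == 0.0

    def test_triangles_with_bridge(self):
        g = two_triangles(bridge=True)
        part = Partition({0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        # m=7, e_12 = 1/7, a_1 = 7/14
        assert vq_index(g, part) == pytest.approx(1 / 7 - 1 / 4)


class TestVosCluster:
    def test_disjoint_cliques_separate(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = vos_cluster(g, seed=0)
        assert part.c == 2
        assert len({part.assignment[n] for n in range(4)}) == 1

    def test_ring_of_four_cliques(self):
        g = nx.ring_of_cliques(4, 4)
        part = vos_cluster(g, resolution=1.0, seed=0)
        assert part.c == 4

    def test_seeded_determinism(self):
        g = nx.ring_of_cliques(4, 4)
        a = vos_cluster(g, seed=7)
        b = vos_cluster(g, seed=7)
        assert a.assignment == b.assignment


class TestFgc:
    def test_two_disjoint_triangles(self):
        g = two_triangles()
        part, q = fgc(g)
        assert q == pytest.approx(0.5)
        assert part.c == 2

    def test_star_collapses_to_single_community(self):
        part, q = fgc(nx.star_graph(5))
        assert q == 0.0
        assert part.c == 1

    def test_empty_edge_graph_raises(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            fgc(g)

    def test_never_beats_exhaustive_search(self):
        g = nx.gnm_random_graph(8, 13, seed=2)
        _, q = fgc(g)
        nodes = list(g.nodes)
        best = -1.0
        # all partitions of 8 nodes into <= 4 blocks via assignment vectors
        for assign in itertools.product(range(4), repeat=len(nodes)):
            part = Partition(dict(zip(nodes, [a + 1 for a in assign])))
            best = max(best, ng_modularity(g, part))
        assert q <= best + 1e-12


class TestAgePartition:
    @pytest.mark.parametrize("nd,expected", [(0.0, 1), (1.0, 10), (0.65, 7),
                                             (0.09999, 1), (0.1, 2)])
    def test_bins(self, nd, expected):
        part = age_partition({"x": nd})
        assert part.assignment["x"] == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            age_partition({"x": 1.5})


class TestHeatmapBundle:
    def test_modularity_matrix_rows_sum_to_zero(self):
        g = two_triangles(bridge=True)
        hb = heatmap_bundle(g, 0.4)
        assert np.allclose(hb.raw.sum(axis=1), 0.0)

    def test_top_split_separates_triangles(self):
        g = two_triangles()
        hb = heatmap_bundle(g, 0.5)
        order = hb.order
        first3 = set(order[:3])
        assert first3 in ({0, 1, 2}, {3, 4, 5})

    def test_dendrogram_heights_non_decreasing(self):
        g = nx.gnm_random_graph(10, 20, seed=3)
        hb = heatmap_bundle(g, 0.3)
        heights = hb.dendrogram[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_edgeless_graph_propagates_error(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            heatmap_bundle(g, 0.1)


class TestReport:
    def test_all_indices_in_range(self):
        g = two_triangles(bridge=True)
        nd = {n: n / 10 for n in g.nodes}
        nx.set_node_attributes(g, nd, "nd")
        rep = modularity_report(g, nd, event=1, nd=0.5, seed=0)
        assert 0 < rep.c_ratio <= 1
        assert 0 <= rep.c_avg <= 1
        assert 0 <= rep.fgc_q <= 1
        assert -1 <= rep.ng_age <= 1
        assert -1 <= rep.ng_vos <= 1
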
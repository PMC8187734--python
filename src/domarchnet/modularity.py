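"""Modularity indices, community detection and modularity heatmaps.

Six indices summarise the modular structure of each (undirected, weighted)
cumulative snapshot:

* **VQ** — the layout quality index Σ_{i<j} (e_ij − a_i²) over community
  pairs, where e_ij is the fraction of edge weight crossing communities i
  and j and a_i = k_i / 2m the weighted-degree fraction of community i.
  This printed form differs from standard Newman–Girvan modularity (which
  sums e_ii − a_i² over single communities); both are reported.
* **C-ratio** — number of detected communities over number of connected
  (degree ≥ 1) nodes.
* **C** — average clustering coefficient of the simplified
  (undirected/unweighted) graph.
* **FGC** — best modularity reached by fast-greedy agglomeration.
* **NG_age / NG_vos** — weighted Newman–Girvan modularity of the partition
  induced by 10 equal-width age bins, and of the partition found by
  resolution-parameterized local-moving clustering, respectively.

Heatmaps visualise the modularity matrix B = A − k kᵀ/2m scaled by a
sign-preserving log10 transform of the network-wide modularity index, with
rows clustered by Ward's minimum-variance method on squared Euclidean
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_comm
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Partition",
    "ModularityReport",
    "HeatmapBundle",
    "clustering_coefficient",
    "ng_modularity",
    "vos_cluster",
    "vq_index",
    "fgc",
    "age_partition",
    "heatmap_bundle",
    "modularity_report",
]


@dataclass
class Partition:
    """Node → community id map, every node assigned.

    Detected communities carry contiguous ids from 1 (``relabel=True``,
    the default); semantic partitions such as age bins may keep their
    original ids, with gaps where a bin is empty (``relabel=False``).
    """

    assignment: dict
    relabel: bool = True

    def __post_init__(self) -> None:
        if not self.relabel:
            return
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(1, len(ids) + 1)):
            remap = {old: i for i, old in enumerate(ids, start=1)}
            self.assignment = {n: remap[c] for n, c in self.assignment.items()}

    @property
    def c(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, cid in self.assignment.items():
            out.setdefault(cid, set()).add(n)
        return [out[c] for c in sorted(out)]


@dataclass
class ModularityReport:
    event: int
    nd: float
    vq: float
    c_ratio: float
    c_avg: float
    fgc_q: float
    ng_age: float
    ng_vos: float
    n_communities: int


@dataclass
class HeatmapBundle:
    nodes: list
    raw: np.ndarray  # modularity matrix B = A - k k^T / 2m
    matrix: np.ndarray  # B after the global-modularity scaling
    distances: np.ndarray  # squared Euclidean row distances (square form)
    dendrogram: np.ndarray  # scipy linkage matrix (Ward)
    order: list  # leaf order, age-sorted within clusters


def _check_edges(graph: nx.Graph) -> float:
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    m = graph.size(weight="weight")
    if m <= 0:
        raise ValueError("graph has no edges")
    return m


def clustering_coefficient(graph: nx.Graph) -> float:
    """Node-averaged local clustering coefficient of a simplified graph.

    Weights and directions are ignored even if present; nodes of degree < 2
    contribute 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    simple = nx.Graph(graph)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    return nx.average_clustering(simple, count_zeros=True)


def ng_modularity(graph: nx.Graph, part: Partition) -> float:
    """Weighted Newman–Girvan modularity Q of a given partition.

    Q = 1/(2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j) with weighted degrees
    k and m the total edge weight.
    """
    m = _check_edges(graph)
    comms = part.communities()
    return nx_comm.modularity(graph, comms, weight="weight")


def vos_cluster(
    graph: nx.Graph, resolution: float = 1.0, *, seed: int = 0
) -> Partition:
    """Similarity-based community detection by seeded local moving.

    Iteratively moves nodes between communities to maximise a
    resolution-parameterized modularity quality, treating edge weights as
    similarities; deterministic for a fixed seed.  Connected components are
    handled independently by construction of the objective.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        return Partition({n: i for i, n in enumerate(sorted(graph.nodes), 1)})
    comms = nx_comm.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    assignment = {}
    for cid, nodes in enumerate(sorted(comms, key=lambda s: sorted(map(str, s))), 1):
        for n in nodes:
            assignment[n] = cid
    return Partition(assignment)


def vq_index(graph: nx.Graph, part: Partition) -> float:
    """Layout quality VQ = Σ_{i<j} (e_ij − a_i²) over community pairs.

    e_ij is the fraction of total edge weight with one endpoint in
    community i and the other in j; a_i = k_i / 2m.  A single community
    gives an empty sum (0).  Implemented literally as printed, which can be
    negative; standard modularity is available via :func:`ng_modularity`.
    """
    m = _check_edges(graph)
    comms = part.communities()
    c = len(comms)
    idx = {}
    for i, nodes in enumerate(comms):
        for n in nodes:
            idx[n] = i
    e = np.zeros((c, c))
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1)
        i, j = idx[u], idx[v]
        e[i, j] += w
        if i != j:
            e[j, i] += w
    e /= 2.0 * m  # intra stored once => e_ii counts half; cross symmetric
    k = np.zeros(c)
    for n in graph.nodes:
        k[idx[n]] += graph.degree(n, weight="weight")
    a = k / (2.0 * m)
    total = 0.0
    for i in range(c):
        for j in range(i + 1, c):
            total += 2.0 * e[i, j] - a[i] ** 2
    return total


def fgc(graph: nx.Graph) -> tuple[Partition, float]:
    """Fast-greedy agglomerative community detection (best-Q cut).

    Returns the partition of the merge dendrogram with maximal modularity;
    when no split improves on a single community (best Q ≤ 0) the whole
    graph is one community with Q = 0.
    """
    _check_edges(graph)
    comms = [set(c) for c in nx_comm.greedy_modularity_communities(
        graph, weight="weight")]
    q = nx_comm.modularity(graph, comms, weight="weight")
    if q <= 0:
        comms = [set(graph.nodes)]
        q = 0.0
    assignment = {}
    for cid, nodes in enumerate(sorted(comms, key=lambda s: sorted(map(str, s))), 1):
        for n in nodes:
            assignment[n] = cid
    return Partition(assignment), float(q)


def age_partition(node_nd: dict, n_bins: int = 10) -> Partition:
    """Equal-width age bins over [0, 1]; the last bin is right-closed."""
    assignment = {}
    for node, nd in node_nd.items():
        if not 0.0 <= nd <= 1.0:
            raise ValueError(f"nd out of [0,1] for {node!r}: {nd}")
        b = min(int(nd * n_bins) + 1, n_bins)
        assignment[node] = b
    return Partition(assignment, relabel=False)


def heatmap_bundle(
    graph: nx.Graph, global_q: float, *, scale: float = 10.0
) -> HeatmapBundle:
    """Modularity-matrix heatmap inputs with a Ward dendrogram.

    B_ij = A_ij − k_i k_j / 2m (rows sum to zero).  The displayed matrix is
    B multiplied by sign(global_q) · log10(1 + |global_q| · scale), an
    order-preserving sign-preserving transform of the network-wide
    modularity index.  Row dissimilarities are squared Euclidean distances;
    the merge tree uses Ward's minimum-variance linkage, and the leaf order
    is age-sorted within each cluster when node ``nd`` attributes exist.
    """
    m = _check_edges(graph)
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / (2.0 * m)
    factor = np.sign(global_q) * np.log10(1.0 + abs(global_q) * scale)
    mat = b * factor if factor != 0 else b.copy()
    dist_sq = squareform(pdist(b, metric="sqeuclidean"))
    z = linkage(b, method="ward")
    order = [nodes[i] for i in leaves_list(z)]
    nd = nx.get_node_attributes(graph, "nd")
    if nd:
        # stable age sort inside each flat 2-cluster split of the dendrogram
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(z, t=2, criterion="maxclust")
        cluster_of = {nodes[i]: flat[i] for i in range(len(nodes))}
        seen = []
        for cid in dict.fromkeys(cluster_of[n] for n in order):
            members = [n for n in order if cluster_of[n] == cid]
            members.sort(key=lambda n: (nd.get(n, 0.0), str(n)))
            seen.extend(members)
        order = seen
    return HeatmapBundle(nodes, b, mat, dist_sq, z, order)


def modularity_report(
    graph: nx.Graph,
    node_nd: dict,
    *,
    event: int = 0,
    nd: float = float("nan"),
    resolution: float = 1.0,
    seed: int = 0,
    n_age_bins: int = 10,
) -> ModularityReport:
    """All six indices for one undirected weighted snapshot."""
    _check_edges(graph)
    vos = vos_cluster(graph, resolution, seed=seed)
    vq = vq_index(graph, vos)
    connected = sum(1 for n in graph.nodes if graph.degree(n) > 0)
    c_ratio = vos.c / connected if connected else float("nan")
    c_avg = clustering_coefficient(graph)
    _, fgc_q = fgc(graph)
    agep = age_partition({n: node_nd[n] for n in graph.nodes}, n_age_bins)
    ng_age = ng_modularity(graph, agep)
    ng_vos = ng_modularity(graph, vos)
    return ModularityReport(
        event, nd, vq, c_ratio, c_avg, fgc_q, ng_age, ng_vos, vos.c
    )
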
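"""Chronological layouts (waterfall, radial), the radial toy model, and
Pajek-format round-tripping.

The radial toy model is the closed-form growth pattern used to illustrate
orbital network expansion: at time t, orbital r (0-based) holds r + 1
nodes, one representative of which sends an outward link to each younger
orbital, so o = t − r − 1, i = r, nodes total t(t + 1)/2 and links total
t(t − 1)/2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chronology import Timeline
from .modularity import Partition

__all__ = [
    "RadialToyState",
    "LayoutCoords",
    "radial_toy",
    "radial_toy_orbitals",
    "waterfall_coords",
    "radial_coords",
    "reduce_network",
    "write_pajek_net",
    "read_pajek_net",
    "write_pajek_clu",
    "write_layout_svg",
]


@dataclass(frozen=True)
class RadialToyState:
    t: int
    r: int
    nodes_in_orbital: int  # r + 1
    outward: int  # t - r - 1
    inward: int  # r


@dataclass
class LayoutCoords:
    xy: dict  # node -> (x, y)
    width: dict  # symbol width  ∝ weighted outdegree
    height: dict  # symbol height ∝ weighted indegree


def radial_toy(t: int) -> tuple[int, int]:
    """Node and link counts of the orbital toy network at time t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return t * (t + 1) // 2, t * (t - 1) // 2


def radial_toy_orbitals(t: int) -> list[RadialToyState]:
    if t < 1:
        raise ValueError("t must be >= 1")
    return [RadialToyState(t, r, r + 1, t - r - 1, r) for r in range(t)]


# ---------------------------------------------------------------------------
# symbol scaling presets (different figures use different shifts)
# ---------------------------------------------------------------------------

_SCALES = {
    "fig2": lambda d: d + 10.0,  # shift so 0-degree nodes stay visible
    "fig3": lambda d: d * 2.0 + 2.0,
}


def _symbol_sizes(g: nx.DiGraph, preset: str):
    try:
        f = _SCALES[preset]
    except KeyError:
        raise ValueError(f"unknown scaling preset {preset!r}")
    width = {v: f(g.out_degree(v, weight="weight")) for v in g.nodes}
    height = {v: f(g.in_degree(v, weight="weight")) for v in g.nodes}
    return width, height


def waterfall_coords(
    snapshot: nx.DiGraph,
    partition: Partition | None = None,
    *,
    preset: str = "fig3",
    row_gap: float = 1.0,
    band_gap: float = 10.0,
) -> LayoutCoords:
    """Top-down-by-age layout: y strictly non-increasing with nd, equal-age
    nodes share a row, x grouped into disjoint community bands."""
    nd = nx.get_node_attributes(snapshot, "nd")
    if len(nd) != snapshot.number_of_nodes():
        raise ValueError("all nodes need an 'nd' attribute")
    ages = sorted(set(nd.values()))
    row = {a: i for i, a in enumerate(ages)}
    if partition is None:
        partition = Partition({v: 1 for v in snapshot.nodes})
    comm = partition.assignment
    xy = {}
    offset: dict[tuple[int, int], int] = {}
    for v in sorted(snapshot.nodes, key=lambda v: (comm[v], nd[v], str(v))):
        c = comm[v]
        r = row[nd[v]]
        k = offset.get((c, r), 0)
        offset[(c, r)] = k + 1
        xy[v] = ((c - 1) * band_gap + k, -r * row_gap)
    width, height = _symbol_sizes(snapshot, preset)
    return LayoutCoords(xy, width, height)


def radial_coords(
    snapshot: nx.DiGraph, timeline: Timeline, *, preset: str = "fig2"
) -> LayoutCoords:
    """Concentric layout: radius = event ordinal of the node's nd, nodes
    spread deterministically by angle within each orbital."""
    nd = nx.get_node_attributes(snapshot, "nd")
    if len(nd) != snapshot.number_of_nodes():
        raise ValueError("all nodes need an 'nd' attribute")
    by_orbital: dict[int, list] = {}
    for v in sorted(snapshot.nodes, key=str):
        by_orbital.setdefault(timeline.event_of(nd[v]), []).append(v)
    xy = {}
    for radius, members in by_orbital.items():
        n = len(members)
        for i, v in enumerate(members):
            theta = 2.0 * math.pi * i / n
            xy[v] = (radius * math.cos(theta), radius * math.sin(theta))
    width, height = _symbol_sizes(snapshot, preset)
    return LayoutCoords(xy, width, height)


def reduce_network(snapshot: nx.DiGraph, pct: float = 99.0) -> nx.DiGraph:
    """Keep nodes whose combined weighted (out + in) degree reaches the
    pct-percentile of the whole snapshot, plus the arcs among them."""
    if snapshot.number_of_nodes() == 0:
        return snapshot.copy()
    combined = {
        v: snapshot.out_degree(v, weight="weight")
        + snapshot.in_degree(v, weight="weight")
        for v in snapshot.nodes
    }
    thr = float(np.percentile(np.array(list(combined.values()), dtype=float), pct))
    keep = [v for v, d in combined.items() if d >= thr]
    return snapshot.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Pajek round-trip
# ---------------------------------------------------------------------------


def write_pajek_net(g: nx.DiGraph, path) -> None:
    """Pajek NET with node nd recorded as a trailing comment per vertex."""
    nodes = sorted(g.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes, start=1)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for v in nodes:
            nd = g.nodes[v].get("nd", 0.0)
            fh.write(f'{index[v]} "{v}" %nd={nd:.7f}\n')
        fh.write("*Arcs\n")
        for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{index[u]} {index[v]} {data.get('weight', 1)}\n")


_VERT_RE = re.compile(r'^(\d+)\s+"([^"]*)"(?:\s+%nd=([0-9.eE+-]+))?\s*$')


def read_pajek_net(path) -> nx.DiGraph:
    g = nx.DiGraph()
    mode = None
    index: dict[int, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                mode = "v"
                continue
            if low.startswith("*arcs") or low.startswith("*edges"):
                mode = "a"
                continue
            if mode == "v":
                m = _VERT_RE.match(line)
                if not m:
                    raise ValueError(f"bad Pajek vertex line: {line!r}")
                i, label, nd = int(m.group(1)), m.group(2), m.group(3)
                index[i] = label
                g.add_node(label, nd=float(nd) if nd is not None else 0.0)
            elif mode == "a":
                parts = line.split()
                u, v = index[int(parts[0])], index[int(parts[1])]
                w = float(parts[2]) if len(parts) > 2 else 1.0
                w = int(w) if w.is_integer() else w
                g.add_edge(u, v, weight=w)
    return g


def write_pajek_clu(partition: Partition, nodes, path) -> None:
    """Pajek CLU partition file in the given node order."""
    nodes = list(nodes)
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for v in nodes:
            fh.write(f"{partition.assignment[v]}\n")


def write_layout_svg(
    snapshot: nx.DiGraph, coords: LayoutCoords, path, *, node_scale: float = 0.1
) -> None:
    """Render a layout to SVG (matplotlib backend, no display needed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v in snapshot.edges:
        x0, y0 = coords.xy[u]
        x1, y1 = coords.xy[v]
        ax.plot([x0, x1], [y0, y1], lw=0.3, color="0.6", zorder=1)
    xs = [coords.xy[v][0] for v in snapshot.nodes]
    ys = [coords.xy[v][1] for v in snapshot.nodes]
    nd = nx.get_node_attributes(snapshot, "nd")
    colors = [nd.get(v, 0.0) for v in snapshot.nodes]
    sizes = [
        node_scale * coords.width[v] * coords.height[v] for v in snapshot.nodes
    ]
    ax.scatter(xs, ys, s=sizes, c=colors, cmap="rainbow", zorder=2)
    ax.set_axis_off()
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
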
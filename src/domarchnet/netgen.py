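"""Construction of the five evolving networks of domain organization.

Five operative criteria turn an entity set of architectures plus an age map
into time-stamped directed graphs:

* **CX** (composition): every entity that occurs as a contiguous proper
  sub-sequence of a multi-block container is linked to that container, one
  arc per (component, container) pair, weighted by the number of distinct
  occurrences.  Supradomain→multidomain containment links are included.
* **PX** (pairwise): multidomain entities are decomposed into unordered
  pairs of domain/supradomain components whose occurrences are disjoint
  (non-overlapping) in the chain; weight counts inducing multidomains.
* **PAX** (pairwise adjacent): PX restricted to pairs whose occurrences abut
  (the end of one is the start of the other).
* **SPX** (spliced pairwise): nodes are the single FSF tokens spliced out of
  all architectures; multidomains induce links between every unordered pair
  of distinct tokens they contain.
* **SPAX** (spliced pairwise adjacent): SPX restricted to consecutive token
  positions.

Arcs are directed from the older to the younger endpoint; an arc's age is
borrowed from the younger node, so a link enters the chronology at the
event where its youngest member first appears.  Equal-age links are kept
but flagged contemporary.  Self-pairs (one token paired with itself) are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .ccs_entities import Architecture, EntitySet, component_occurrences
from .chronology import ND_DECIMALS, AgeMap, Timeline, make_timeline

__all__ = [
    "CRITERIA",
    "Arc",
    "EvolvingNetwork",
    "build_network",
    "snapshot",
    "undirected_snapshot",
    "degrees_at",
    "degree_series",
    "first_events",
    "write_edge_tsv",
]

CRITERIA = ("CX", "PX", "PAX", "SPX", "SPAX")


@dataclass(frozen=True)
class Arc:
    """A time-directed, multiplicity-weighted link."""

    source: str  # older endpoint (or canonical order when contemporary)
    target: str  # younger endpoint
    weight: int
    age: float  # nd of the younger endpoint
    contemporary: bool  # endpoints share the same nd


@dataclass
class EvolvingNetwork:
    criterion: str
    nodes: dict[str, float]  # label -> nd
    arcs: list[Arc]
    timeline: Timeline = field(init=False)

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for a in self.arcs:
            if a.source not in self.nodes or a.target not in self.nodes:
                raise ValueError(f"arc endpoint not in node set: {a}")
        self.timeline = make_timeline(AgeMap(self.nodes))

    @property
    def n_events(self) -> int:
        return len(self.timeline)


def _require_ages(labels, ages: AgeMap) -> None:
    for lab in labels:
        if lab not in ages:
            raise KeyError(f"entity {lab!r} has no age")


def _orient(a: str, b: str, nd_a: float, nd_b: float) -> tuple[str, str, bool]:
    """Old→new orientation; contemporary ties keep (a, b) order."""
    if nd_a < nd_b:
        return a, b, False
    if nd_b < nd_a:
        return b, a, False
    return a, b, True


def _rounded(nd: float) -> float:
    return round(nd, ND_DECIMALS)


def build_network(criterion: str, eset: EntitySet, ages: AgeMap) -> EvolvingNetwork:
    """Build one of the five evolving networks from a classified entity set."""
    criterion = criterion.upper()
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    _require_ages((e.label for e in eset), ages)
    ent_nd = {e.label: _rounded(ages[e.label]) for e in eset}

    if criterion == "CX":
        return _build_cx(eset, ent_nd)
    if criterion in ("PX", "PAX"):
        return _build_pairwise(criterion, eset, ent_nd)
    return _build_spliced(criterion, eset, ent_nd)


def _build_cx(eset: EntitySet, ent_nd: dict[str, float]) -> EvolvingNetwork:
    nodes = dict(ent_nd)
    arcs: list[Arc] = []
    for container in eset:
        if len(container.blocks) < 2:
            continue
        counts: dict[str, int] = {}
        for lbl, _, _ in component_occurrences(container, eset):
            counts[lbl] = counts.get(lbl, 0) + 1
        for comp, w in sorted(counts.items()):
            s, t, contemp = _orient(
                comp, container.label, ent_nd[comp], ent_nd[container.label]
            )
            arcs.append(
                Arc(s, t, w, max(ent_nd[comp], ent_nd[container.label]), contemp)
            )
    return EvolvingNetwork("CX", nodes, arcs)


def _pairs_from_occurrences(
    occs: list[tuple[str, int, int]], adjacent: bool
) -> set[tuple[str, str]]:
    """Unordered distinct-label pairs with disjoint (optionally abutting)
    occurrences."""
    pairs: set[tuple[str, str]] = set()
    for i in range(len(occs)):
        li, si, ei = occs[i]
        for j in range(i + 1, len(occs)):
            lj, sj, ej = occs[j]
            if li == lj:
                continue
            disjoint = ei <= sj or ej <= si
            if not disjoint:
                continue
            if adjacent and not (ei == sj or ej == si):
                continue
            pairs.add((li, lj) if li <= lj else (lj, li))
    return pairs


def _build_pairwise(
    criterion: str, eset: EntitySet, ent_nd: dict[str, float]
) -> EvolvingNetwork:
    adjacent = criterion == "PAX"
    node_kinds = ("domain", "supradomain")
    nodes = {
        e.label: ent_nd[e.label] for e in eset if eset.kind[e.label] in node_kinds
    }
    weights: dict[tuple[str, str], int] = {}
    for container in eset:
        if eset.kind[container.label] != "multidomain":
            continue
        occs = [
            (lbl, s, e)
            for lbl, s, e in component_occurrences(container, eset)
            if eset.kind[lbl] in node_kinds
        ]
        for pair in _pairs_from_occurrences(occs, adjacent):
            weights[pair] = weights.get(pair, 0) + 1
    arcs = _pairs_to_arcs(weights, nodes)
    return EvolvingNetwork(criterion, nodes, arcs)


def _build_spliced(
    criterion: str, eset: EntitySet, ent_nd: dict[str, float]
) -> EvolvingNetwork:
    adjacent = criterion == "SPAX"
    # Token ages: first appearance = min nd over entities carrying the token.
    nodes: dict[str, float] = {}
    for ent in eset:
        nd = ent_nd[ent.label]
        for tok in ent.tokens:
            if tok not in nodes or nd < nodes[tok]:
                nodes[tok] = nd
    weights: dict[tuple[str, str], int] = {}
    for container in eset:
        if eset.kind[container.label] != "multidomain":
            continue
        toks = container.tokens
        pairs: set[tuple[str, str]] = set()
        if adjacent:
            it = ((i, i + 1) for i in range(len(toks) - 1))
        else:
            it = ((i, j) for i in range(len(toks)) for j in range(i + 1, len(toks)))
        for i, j in it:
            if toks[i] == toks[j]:
                continue
            a, b = toks[i], toks[j]
            pairs.add((a, b) if a <= b else (b, a))
        for pair in pairs:
            weights[pair] = weights.get(pair, 0) + 1
    arcs = _pairs_to_arcs(weights, nodes)
    return EvolvingNetwork(criterion, nodes, arcs)


def _pairs_to_arcs(
    weights: dict[tuple[str, str], int], nodes: dict[str, float]
) -> list[Arc]:
    arcs = []
    for (a, b), w in sorted(weights.items()):
        s, t, contemp = _orient(a, b, nodes[a], nodes[b])
        arcs.append(Arc(s, t, w, max(nodes[a], nodes[b]), contemp))
    return arcs


# ---------------------------------------------------------------------------
# snapshots and degree accounting
# ---------------------------------------------------------------------------


def snapshot(net: EvolvingNetwork, event: int) -> nx.DiGraph:
    """Cumulative directed snapshot at a 1-based event ordinal.

    Contains every node with nd ≤ nd_event and every arc whose age (younger
    endpoint's nd) ≤ nd_event, contemporary arcs included.
    """
    if not 1 <= event <= len(net.timeline):
        raise ValueError(f"event {event} out of range 1..{len(net.timeline)}")
    cutoff = net.timeline.events[event - 1]
    g = nx.DiGraph(criterion=net.criterion, nd=cutoff, event=event)
    for lab, nd in net.nodes.items():
        if nd <= cutoff:
            g.add_node(lab, nd=nd)
    for a in net.arcs:
        if a.age <= cutoff:
            g.add_edge(
                a.source, a.target,
                weight=a.weight, age=a.age, contemporary=a.contemporary,
            )
    return g


def undirected_snapshot(
    net: EvolvingNetwork,
    event: int,
    *,
    weighted: bool = True,
    include_contemporary: bool = True,
) -> nx.Graph:
    """Simplified (undirected) snapshot for modularity/clustering statistics."""
    d = snapshot(net, event)
    g = nx.Graph(**d.graph)
    g.add_nodes_from(d.nodes(data=True))
    for u, v, data in d.edges(data=True):
        if not include_contemporary and data["contemporary"]:
            continue
        w = data["weight"] if weighted else 1
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def degrees_at(net: EvolvingNetwork, event: int) -> pd.DataFrame:
    """Per-node cumulative degree record at one event.

    Columns: label, event, outdegree, indegree, w_outdegree, w_indegree.
    """
    g = snapshot(net, event)
    rows = []
    for node in sorted(g.nodes):
        rows.append(
            {
                "label": node,
                "event": event,
                "outdegree": g.out_degree(node),
                "indegree": g.in_degree(node),
                "w_outdegree": g.out_degree(node, weight="weight"),
                "w_indegree": g.in_degree(node, weight="weight"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "event", "outdegree", "indegree",
                 "w_outdegree", "w_indegree"],
    )


def degree_series(net: EvolvingNetwork, events=None) -> pd.DataFrame:
    """Concatenated :func:`degrees_at` over events (default: all)."""
    if events is None:
        events = range(1, len(net.timeline) + 1)
    frames = [degrees_at(net, e) for e in events]
    return pd.concat(frames, ignore_index=True)


def first_events(net: EvolvingNetwork) -> tuple[Arc, float]:
    """The earliest non-contemporary arc and its nd.

    Ties among equally old arcs are broken lexicographically by
    (source, target).
    """
    candidates = [a for a in net.arcs if not a.contemporary]
    if not candidates:
        raise ValueError("network has no non-contemporary arcs")
    best = min(candidates, key=lambda a: (a.age, a.source, a.target))
    return best, best.age


def write_edge_tsv(net: EvolvingNetwork, path) -> None:
    """TSV edge list: source, target, weight, age, contemporary."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tage\tcontemporary\n")
        for a in net.arcs:
            fh.write(
                f"{a.source}\t{a.target}\t{a.weight}\t{a.age:.7f}\t"
                f"{int(a.contemporary)}\n"
            )
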
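"""Donor/acceptor hub ranking across the five evolving networks.

A hub at a time point is a node whose *combined* weighted degree — the sum
of its weighted outdegree (donor role) or indegree (acceptor role) over the
five networks' snapshots — reaches a percentile threshold (99.9th by
default) of the combined degrees of all nodes.  The percentile is computed
by linear interpolation over the full combined-degree vector, zero-degree
nodes included, which is why published thresholds can be fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ccs_entities import read_scop_descriptions
from .netgen import EvolvingNetwork, snapshot

__all__ = ["HubRecord", "hub_table", "hub_threshold", "annotate", "write_hub_tsv"]


@dataclass
class HubRecord:
    label: str
    age_rank: int
    nd: float
    networks: list[str]
    degrees: dict[str, float]
    combined: float
    fusional_fissional: str = "N/A"
    description: str = "N/A"
    go_name: str = "N/A"
    direction: str = "out"
    extras: dict = field(default_factory=dict)


def _combined_degrees(nets, nd_point, direction):
    """Per-node combined weighted degree over the five networks at the
    latest event with nd ≤ nd_point; per-network contributions kept."""
    per_net: dict[str, dict[str, float]] = {}
    all_nodes: dict[str, float] = {}
    for crit, net in nets.items():
        ev = net.timeline.event_of(nd_point)
        g = snapshot(net, ev)
        deg = {}
        for v in g.nodes:
            if direction == "out":
                deg[v] = g.out_degree(v, weight="weight")
            else:
                deg[v] = g.in_degree(v, weight="weight")
            nd = g.nodes[v]["nd"]
            if v not in all_nodes or nd < all_nodes[v]:
                all_nodes[v] = nd
        per_net[crit] = deg
    combined = {
        v: sum(per_net[c].get(v, 0.0) for c in per_net) for v in all_nodes
    }
    return combined, per_net, all_nodes


def hub_threshold(combined: dict[str, float], pct: float) -> float:
    return float(np.percentile(np.array(list(combined.values()), dtype=float), pct))


def hub_table(
    nets: dict[str, EvolvingNetwork],
    nd_point: float = 1.0,
    direction: str = "out",
    pct: float = 99.9,
) -> tuple[list[HubRecord], float]:
    """Rank hubs by combined weighted degree at a time point.

    Returns the records (combined degree ≥ threshold, sorted descending)
    and the interpolated percentile threshold.  ``networks`` lists, per
    hub, the criteria whose own per-network degree also reaches that
    network's pct-percentile, sorted by degree descending.
    """
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    if not nets:
        raise ValueError("no networks given")
    for net in nets.values():
        if not net.nodes:
            raise ValueError("empty network")
    combined, per_net, all_nodes = _combined_degrees(nets, nd_point, direction)
    thr = hub_threshold(combined, pct)
    # per-network thresholds decide which criteria a hub is listed under
    net_thr = {
        c: float(np.percentile(np.array(list(d.values()), dtype=float), pct))
        if d else 0.0
        for c, d in per_net.items()
    }
    # age rank: 1-based ordinal of first appearance over all nodes
    order = sorted(all_nodes, key=lambda v: (all_nodes[v], v))
    age_rank = {v: i for i, v in enumerate(order, start=1)}
    records = []
    for v, cd in combined.items():
        if cd < thr:
            continue
        degs = {c: per_net[c].get(v, 0.0) for c in per_net}
        listed = [
            c for c in sorted(degs, key=lambda c: -degs[c])
            if degs[c] >= net_thr[c] and degs[c] > 0
        ]
        records.append(
            HubRecord(
                label=v, age_rank=age_rank[v], nd=all_nodes[v],
                networks=listed, degrees=degs, combined=cd,
                direction=direction,
            )
        )
    records.sort(key=lambda r: (-r.combined, r.label))
    return records, thr


def _read_go_tsv(path) -> dict[str, str]:
    """SUPFAM Domain2GO dialect: tab-separated with an sccs (or sunid) key
    in the first column and the GO term name in the last column; ``#``
    comments ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            out.setdefault(parts[0].strip(), parts[-1].strip())
    return out


def annotate(
    records: list[HubRecord],
    scop_des_path=None,
    go_path=None,
) -> list[HubRecord]:
    """Left-join SCOP descriptions and GO names onto hub records.

    Only single-domain labels carry SCOP/GO annotations; composites keep
    "N/A".  A label absent from the files is "N/A", not an error.
    """
    desc = read_scop_descriptions(scop_des_path) if scop_des_path else {}
    go = _read_go_tsv(go_path) if go_path else {}
    for r in records:
        if "|" in r.label:
            continue
        core = r.label.rstrip("&")
        r.description = desc.get(core, "N/A")
        r.go_name = go.get(core, "N/A")
    return records


def write_hub_tsv(records: list[HubRecord], path) -> None:
    cols = [
        "age_rank", "label", "nd", "networks", "degrees", "combined",
        "fusional_fissional", "description", "go_name",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            degs = ", ".join(f"{c}={r.degrees[c]:g}" for c in r.networks)
            fh.write(
                f"{r.age_rank}\t{r.label}\t{r.nd:.7f}\t"
                f"{', '.join(r.networks)}\t{degs}\t{r.combined:g}\t"
                f"{r.fusional_fissional}\t{r.description}\t{r.go_name}\n"
            )
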
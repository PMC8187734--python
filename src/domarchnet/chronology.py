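"""Relative ages (node distances) and the discrete evolutionary timeline.

The age of first appearance of each architecture is read off a rooted
phylogenomic tree whose leaves are the architectures: the node distance (nd)
of a leaf is the number of internal nodes on its root-to-leaf path (root
included), min-max rescaled to [0, 1].  Only tree imbalance carries the
signal — branch lengths are ignored.  Distinct nd values define the discrete
"time events" that index every evolving-network snapshot.  An affine
molecular clock of fold structures, t = -3.831*nd + 3.628, converts nd into
geological ages in billions of years ago (Gya).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = [
    "AgeMap",
    "Timeline",
    "ClockParams",
    "compute_nd",
    "make_timeline",
    "clock_age",
    "read_newick",
    "write_agemap_tsv",
]

#: nd values are rounded to this many decimals before events are formed,
#: matching the precision at which ages are reported; avoids float noise
#: splitting one time sliver into two.
ND_DECIMALS = 7


@dataclass
class AgeMap:
    """Map entity label → relative age nd in [0, 1]."""

    nd: dict[str, float]

    def __getitem__(self, label: str) -> float:
        return self.nd[label]

    def __contains__(self, label: str) -> bool:
        return label in self.nd

    def __len__(self) -> int:
        return len(self.nd)

    def items(self):
        return self.nd.items()


@dataclass
class Timeline:
    """Ascending distinct nd values with 1-based event ordinals."""

    events: list[float]
    index: dict[float, int] = field(init=False)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.events, self.events[1:])):
            raise ValueError("timeline events must be strictly increasing")
        self.index = {nd: i for i, nd in enumerate(self.events, start=1)}

    def __len__(self) -> int:
        return len(self.events)

    def event_of(self, nd: float) -> int:
        """Ordinal of the latest event with value ≤ nd."""
        key = round(nd, ND_DECIMALS)
        if key in self.index:
            return self.index[key]
        ix = 0
        for i, v in enumerate(self.events, start=1):
            if v <= key:
                ix = i
        if ix == 0:
            raise KeyError(f"nd {nd} precedes the first event")
        return ix


@dataclass(frozen=True)
class ClockParams:
    """Affine molecular clock: geological age (Gya) = slope*nd + intercept."""

    slope: float = -3.831  # Gy per nd unit
    intercept: float = 3.628  # Gya at nd = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("clock slope must be negative (older = smaller nd)")


def compute_nd(tree: dendropy.Tree) -> AgeMap:
    """Relative ages from root-to-leaf internal-node counts.

    For each leaf, count internal nodes on the path from the root (included)
    to the leaf, then min-max normalise the counts so the shallowest leaf is
    0 and the deepest is 1.  When all counts are equal every nd is 0.  Branch
    lengths and internal labels play no role.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    root = tree.seed_node
    if len(root.child_nodes()) == 0:
        raise ValueError("tree has no root structure")
    labels = []
    counts = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise ValueError("every leaf must be labeled")
        label = lf.taxon.label
        c = 0
        node = lf.parent_node
        while node is not None:
            c += 1
            node = node.parent_node
        labels.append(label)
        counts.append(c)
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    cmin, cmax = min(counts), max(counts)
    if cmax == cmin:
        nd = {lab: 0.0 for lab in labels}
    else:
        span = cmax - cmin
        nd = {
            lab: round((c - cmin) / span, ND_DECIMALS)
            for lab, c in zip(labels, counts)
        }
    return AgeMap(nd)


def make_timeline(ages: AgeMap) -> Timeline:
    """Distinct nd values in ascending order (dedup at ND_DECIMALS)."""
    if not ages.nd:
        raise ValueError("empty age map")
    events = sorted({round(v, ND_DECIMALS) for v in ages.nd.values()})
    return Timeline(events)


def clock_age(nd: float, params: ClockParams = ClockParams()) -> float:
    """Geological age in Gya for a relative age nd ∈ [0, 1].

    The published clock extrapolates slightly past the present at nd = 1
    (negative Gya); such values are returned as-is rather than clamped, so
    elapsed-time differences remain exact.
    """
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd must be in [0, 1], got {nd}")
    return params.slope * nd + params.intercept


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; quoted labels allowed, branch lengths
    tolerated (and ignored downstream)."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def write_agemap_tsv(ages: AgeMap, path, params: ClockParams = ClockParams()) -> None:
    """Write ``label<TAB>nd<TAB>gya`` (sorted by nd then label)."""
    with open(path, "w") as fh:
        fh.write("label\tnd\tgya\n")
        for label, nd in sorted(ages.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{label}\t{nd:.7f}\t{clock_age(nd, params):.4f}\n")
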
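"""Synthetic entity sets, ages and trees with the statistical shape the
pipeline assumes.

The generator emulates a genomic census of domain organization: a pool of
single domains appearing on a discrete age grid, plus multidomains built by
concatenating domain tokens with "rich-get-richer" reuse — older and
already-popular domains are resampled preferentially, which is what makes
the resulting spliced networks heavy-tailed.  A fraction of multidomains
extend existing multi-block entities, so supradomains (reused
sub-combinations) arise naturally.  Every multidomain is strictly younger
than its components, giving a clean arrow of time; real tree-derived data
need not satisfy this, which the network builder tolerates via the
contemporary flag.

Defaults are scaled to a few hundred domains, a few thousand multidomains
and on the order of a hundred discrete time events — the same orders of
magnitude as a genomic census, at a size every analysis stage can traverse
quickly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .ccs_entities import Architecture, Block, EntitySet, classify_entities
from .chronology import AgeMap

__all__ = ["SynthConfig", "gen_entity_set", "gen_tree", "write_entity_tsv"]

_CLASSES = "abcdefg"


@dataclass(frozen=True)
class SynthConfig:
    n_domains: int = 300
    n_multidomains: int = 3000
    max_blocks: int = 5
    pref_strength: float = 1.0  # reuse ∝ (count)^pref_strength
    repeat_prob: float = 0.05  # chance a sampled token gains the '&' marker
    n_events: int = 169  # target number of distinct age values
    extend_prob: float = 0.25  # chance to extend an existing multidomain
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_domains, self.n_multidomains, self.max_blocks) < 1:
            raise ValueError("counts must be >= 1")
        if self.pref_strength < 0:
            raise ValueError("pref_strength must be >= 0")
        if not 0 <= self.repeat_prob < 1:
            raise ValueError("repeat_prob must be in [0, 1)")
        if self.max_blocks < 2:
            raise ValueError("max_blocks must allow 2-block multidomains")


def _domain_labels(n: int, rng: np.random.Generator) -> list[str]:
    labels: set[str] = set()
    while len(labels) < n:
        cls = _CLASSES[rng.integers(0, len(_CLASSES))]
        labels.add(f"{cls}.{rng.integers(1, 160)}.{rng.integers(1, 30)}")
    return sorted(labels)


def gen_entity_set(cfg: SynthConfig) -> tuple[EntitySet, AgeMap]:
    """Generate a classified entity set and its age map.

    Ages live on an integer event grid: domains occupy roughly the first
    60% of the grid (weighted toward early events), and each multidomain
    sits one grid step after its youngest component, so components always
    predate their containers.  Final nd values are min-max scaled to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    n_grid = cfg.n_events
    if n_grid < 4:
        raise ValueError("n_events too small for a meaningful grid")
    labels = _domain_labels(cfg.n_domains, rng)

    # early-weighted domain ages on the grid
    dom_span = max(2, int(0.6 * n_grid))
    w = np.linspace(1.0, 0.15, dom_span)
    grid_idx = rng.choice(dom_span, size=cfg.n_domains, p=w / w.sum())
    grid_idx[int(rng.integers(cfg.n_domains))] = 0  # anchor the origin
    age_idx: dict[str, int] = {lab: int(g) for lab, g in zip(labels, grid_idx)}

    reuse = np.ones(cfg.n_domains)
    dom_age = grid_idx.astype(float)
    entities: list[Architecture] = [
        Architecture(lab, (Block(lab),)) for lab in labels
    ]
    seen: set[str] = set(labels)
    multis: list[tuple[str, ...]] = []

    def sample_tokens(k: int) -> list[str]:
        wts = reuse**cfg.pref_strength
        wts = wts * (1.0 + (dom_span - dom_age) / dom_span)  # favor older
        p = wts / wts.sum()
        picks = rng.choice(cfg.n_domains, size=k, replace=True, p=p)
        toks = []
        for ix in picks:
            tok = labels[ix]
            if rng.random() < cfg.repeat_prob:
                tok += "&"
            toks.append(tok)
            reuse[ix] += 1
        return toks

    attempts = 0
    while len(multis) < cfg.n_multidomains and attempts < 50 * cfg.n_multidomains:
        attempts += 1
        if multis and rng.random() < cfg.extend_prob:
            base = multis[int(rng.integers(len(multis)))]
            toks = list(base) + sample_tokens(1)
            if len(toks) > cfg.max_blocks:
                toks = toks[: cfg.max_blocks]
        else:
            k = int(rng.integers(2, cfg.max_blocks + 1))
            toks = sample_tokens(k)
        label = "|".join(toks)
        if label in seen:
            continue
        comp_idx = [age_idx[t.rstrip("&")] for t in toks]
        age_idx[label] = max(comp_idx) + 1
        seen.add(label)
        multis.append(tuple(toks))
        entities.append(
            Architecture(
                label,
                tuple(Block(t.rstrip("&"), t.endswith("&")) for t in toks),
            )
        )
    if len(multis) < cfg.n_multidomains:
        raise ValueError("could not generate the requested number of "
                         "unique multidomains; enlarge the domain pool")

    idx_max = max(age_idx.values())
    nd = {lab: round(ix / idx_max, 7) for lab, ix in age_idx.items()}
    return classify_entities(entities), AgeMap(nd)


def gen_tree(
    n_leaves: int, imbalance: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Random rooted tree with tunable imbalance.

    ``imbalance=1`` yields a pure caterpillar (maximal spread of
    root-to-leaf node counts, hence of nd values); ``imbalance=0`` splits
    every leaf set as evenly as possible (a balanced tree where all nd
    collapse to 0).  Intermediate values mix the two split rules per node,
    seeded and deterministic.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if not 0.0 <= imbalance <= 1.0:
        raise ValueError("imbalance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(n_leaves)]

    def newick(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return leaves[0]
        if len(leaves) == 2:
            return f"({leaves[0]},{leaves[1]})"
        if rng.random() < imbalance:
            cut = 1
        else:
            cut = len(leaves) // 2
        return f"({newick(leaves[:cut])},{newick(leaves[cut:])})"

    tree = dendropy.Tree.get(
        data=newick(labels) + ";", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def write_entity_tsv(eset: EntitySet, ages: AgeMap, path) -> None:
    """Write the pipeline's two-column ``label<TAB>nd`` input format."""
    with open(path, "w") as fh:
        fh.write("label\tnd\n")
        for ent in eset:
            fh.write(f"{ent.label}\t{ages[ent.label]:.7f}\n")
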